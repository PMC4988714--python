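"""Gradient-seeded sequential superpixel segmentation (GSLIC).

A SLIC-style local clustering adapted to ordered CT stacks: every pixel
carries a six-dimensional feature [l, a, b, x, y, z]; cluster centres are
seeded on a regular grid, nudged off high-gradient positions, iterated to
convergence on slice 0, and the converged (x, y) positions are handed to
slice z+1 as its initialisation — adjacent CT slices are strongly
correlated, so the hand-over cuts the iterations the later slices need.

CT is single-channel, so the CIELAB embedding is degenerate by design:
stack intensities are min–max scaled to l ∈ [0, 100] and a = b = 0, which
turns the colour distance into a plain intensity distance while keeping
the distance formulas intact.

The pixel-to-centre distance within one slice is

    Ds = (D_lab + δ·D_xy) / (1 + δ²),

with D_lab and D_xy Euclidean in (l, a, b) and (x, y); δ (typically 1–20)
weights spatial proximity against intensity similarity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .stackio import ImageStack, RoiStack, StackValidationError

__all__ = [
    "PixelFeature",
    "ClusterCenter",
    "SuperpixelMap",
    "default_roi_rect",
    "extract_roi",
    "grid_step",
    "gradient",
    "gradient_map",
    "init_centers",
    "pixel_distance",
    "segment_stack",
    "enforce_connectivity",
]

logger = logging.getLogger(__name__)

# ROI corners that contain all lung parenchyma on a 512×512 thorax slice,
# scaled proportionally for other frame sizes.
ROI_512 = (100, 60, 400, 420)

MAX_ITERATIONS = 100


@dataclass(frozen=True)
class PixelFeature:
    l: float
    a: float
    b: float
    x: float
    y: float
    z: float

    def vector(self) -> np.ndarray:
        return np.array([self.l, self.a, self.b, self.x, self.y, self.z])


@dataclass
class ClusterCenter:
    l: float
    a: float
    b: float
    x: float
    y: float
    z: float
    k: int

    def vector(self) -> np.ndarray:
        return np.array([self.l, self.a, self.b, self.x, self.y, self.z])


@dataclass
class SuperpixelMap:
    """Superpixel partition of an ROI stack.

    ``labels[z]`` assigns every ROI pixel of slice z a globally unique
    0-based superpixel id; ``features`` row i is the mean
    [l, a, b, x, y, z] of the pixels labelled i (x, y in ROI coordinates,
    l on the [0, 100] scale).
    """

    labels: list[np.ndarray]
    features: np.ndarray
    S: float
    params: dict
    offset: tuple[int, int] = (0, 0)
    full_shape: tuple[int, int] | None = None
    iterations: list[int] = field(default_factory=list)

    @property
    def n_superpixels(self) -> int:
        return self.features.shape[0]


def default_roi_rect(width: int, height: int) -> tuple[int, int, int, int]:
    """The standard lung ROI rectangle, scaled from the 512×512 convention."""
    x0, y0, x1, y1 = ROI_512
    return (
        round(x0 * width / 512),
        round(y0 * height / 512),
        round(x1 * width / 512),
        round(y1 * height / 512),
    )


def extract_roi(stack: ImageStack, rect: tuple[int, int, int, int] | None = None) -> RoiStack:
    """Crop the stack to the lung ROI rectangle.

    ``rect`` is (x0, y0, x1, y1) with exclusive lower-right corner; the
    default is (100, 60)–(400, 420) at 512×512, scaled proportionally.
    The crop offset is recorded so masks can be re-embedded.
    """
    if rect is None:
        rect = default_roi_rect(stack.width, stack.height)
    x0, y0, x1, y1 = rect
    if not (0 <= x0 < x1 <= stack.width and 0 <= y0 < y1 <= stack.height):
        raise StackValidationError(
            f"ROI rect {rect} outside slice bounds {stack.width}×{stack.height}"
        )
    return RoiStack(
        stack.data[:, y0:y1, x0:x1].copy(),
        offset=(x0, y0),
        full_shape=(stack.height, stack.width),
    )


def grid_step(N: int, K: int) -> float:
    """Average superpixel side length S = sqrt(N / K)."""
    if K < 1:
        raise StackValidationError("superpixel count K must be >= 1")
    if N < K:
        raise StackValidationError(f"need at least K={K} pixels, got N={N}")
    return math.sqrt(N / K)


def gradient(image: np.ndarray, x: int, y: int) -> float:
    """G(x, y) = sqrt([V(x+1,y)−V(x−1,y)]² + [V(x,y+1)−V(x,y−1)]²).

    Border coordinates are clamped (replicate padding).
    """
    h, w = image.shape
    gx = image[y, min(x + 1, w - 1)] - image[y, max(x - 1, 0)]
    gy = image[min(y + 1, h - 1), x] - image[max(y - 1, 0), x]
    return float(np.hypot(gx, gy))


def gradient_map(image: np.ndarray) -> np.ndarray:
    """Vectorised :func:`gradient` over the whole slice."""
    padded = np.pad(image, 1, mode="edge")
    gx = padded[1:-1, 2:] - padded[1:-1, :-2]
    gy = padded[2:, 1:-1] - padded[:-2, 1:-1]
    return np.hypot(gx, gy)


def init_centers(slice_: np.ndarray, S: float, n: int, z: float = 0.0) -> list[ClusterCenter]:
    """Seed one centre per S×S grid cell, nudged to the lowest-gradient pixel.

    Centres start at the exact grid-cell centroid; if a pixel in the n×n
    window around the (rounded) centroid has a strictly lower gradient, the
    centre moves to that pixel (row-major first occurrence breaks ties), so
    centres stay off region edges but keep the unperturbed grid position on
    featureless areas.
    """
    if n % 2 != 1 or n < 1:
        raise StackValidationError("gradient window size n must be odd and >= 1")
    h, w = slice_.shape
    grad = gradient_map(slice_)
    if S > w and S > h:
        # degenerate: a single centre at the global gradient minimum
        iy, ix = np.unravel_index(np.argmin(grad), grad.shape)
        return [ClusterCenter(float(slice_[iy, ix]), 0.0, 0.0, float(ix), float(iy), z, 0)]
    nx = max(1, round(w / S))
    ny = max(1, round(h / S))
    half = n // 2
    centers = []
    k = 0
    for j in range(ny):
        cy = (j + 0.5) * h / ny - 0.5
        for i in range(nx):
            cx = (i + 0.5) * w / nx - 0.5
            px, py = int(round(cx)), int(round(cy))
            win = grad[
                max(py - half, 0) : py + half + 1,
                max(px - half, 0) : px + half + 1,
            ]
            wy, wx = np.unravel_index(np.argmin(win), win.shape)
            gx, gy = max(px - half, 0) + wx, max(py - half, 0) + wy
            if grad[gy, gx] < grad[py, px]:
                cx, cy2 = float(gx), float(gy)
            else:
                cy2 = cy
            ly = int(round(cy2))
            lx = int(round(cx))
            centers.append(
                ClusterCenter(float(slice_[ly, lx]), 0.0, 0.0, float(cx), float(cy2), z, k)
            )
            k += 1
    return centers


def pixel_distance(p: PixelFeature, c: ClusterCenter, delta: float) -> float:
    """Combined similarity Ds between a pixel and a same-slice centre."""
    if delta <= 0:
        raise StackValidationError("delta must be > 0 (typically 1–20)")
    if p.z != c.z:
        raise StackValidationError("pixel and centre must lie on the same slice")
    d_lab = math.sqrt((p.l - c.l) ** 2 + (p.a - c.a) ** 2 + (p.b - c.b) ** 2)
    d_xy = math.hypot(p.x - c.x, p.y - c.y)
    return (d_lab + delta * d_xy) / (1.0 + delta**2)


def _assign_pixels(lmap, cx, cy, cl, S, delta):
    """One assignment sweep: best centre per pixel, searched in 2S×2S windows.

    Centres are visited in ascending id with strict improvement, so ties go
    to the lowest centre id.
    """
    h, w = lmap.shape
    best = np.full((h, w), np.inf)
    labels = np.full((h, w), -1, dtype=np.int32)
    denom = 1.0 + delta**2
    for k in range(len(cx)):
        xlo = max(int(math.floor(cx[k] - S)), 0)
        xhi = min(int(math.ceil(cx[k] + S)) + 1, w)
        ylo = max(int(math.floor(cy[k] - S)), 0)
        yhi = min(int(math.ceil(cy[k] + S)) + 1, h)
        if xlo >= xhi or ylo >= yhi:
            continue
        sub = lmap[ylo:yhi, xlo:xhi]
        ys, xs = np.mgrid[ylo:yhi, xlo:xhi]
        d_lab = np.abs(sub - cl[k])
        d_xy = np.hypot(xs - cx[k], ys - cy[k])
        ds = (d_lab + delta * d_xy) / denom
        better = ds < best[ylo:yhi, xlo:xhi]
        best[ylo:yhi, xlo:xhi][better] = ds[better]
        labels[ylo:yhi, xlo:xhi][better] = k
    uncovered = labels < 0
    if uncovered.any():
        logger.info("%d pixels outside every 2S×2S window; assigning globally", uncovered.sum())
        ys, xs = np.nonzero(uncovered)
        d_lab = np.abs(lmap[ys, xs][:, None] - cl[None, :])
        d_xy = np.hypot(xs[:, None] - cx[None, :], ys[:, None] - cy[None, :])
        ds = (d_lab + delta * d_xy) / denom
        labels[ys, xs] = np.argmin(ds, axis=1)
    return labels


def _segment_slice(lmap, centers_xy_l, S, delta, E, max_iter=MAX_ITERATIONS):
    """Iterate assignment/update on one slice until the centre shift ≤ E.

    Returns (labels, converged centres (x, y, l), iteration count).
    """
    cx, cy, cl = (np.array(v, dtype=float) for v in centers_xy_l)
    n_iter = 0
    for _ in range(max_iter):
        labels = _assign_pixels(lmap, cx, cy, cl, S, delta)
        n_iter += 1
        ncx, ncy, ncl = cx.copy(), cy.copy(), cl.copy()
        counts = np.bincount(labels.ravel(), minlength=len(cx))
        sum_x = np.bincount(labels.ravel(), weights=np.tile(np.arange(lmap.shape[1], dtype=float), lmap.shape[0]), minlength=len(cx))
        sum_y = np.bincount(labels.ravel(), weights=np.repeat(np.arange(lmap.shape[0], dtype=float), lmap.shape[1]), minlength=len(cx))
        sum_l = np.bincount(labels.ravel(), weights=lmap.ravel(), minlength=len(cx))
        nonzero = counts > 0
        ncx[nonzero] = sum_x[nonzero] / counts[nonzero]
        ncy[nonzero] = sum_y[nonzero] / counts[nonzero]
        ncl[nonzero] = sum_l[nonzero] / counts[nonzero]
        residual = np.mean(
            np.sqrt((ncx - cx) ** 2 + (ncy - cy) ** 2 + (ncl - cl) ** 2)
        )
        cx, cy, cl = ncx, ncy, ncl
        if residual <= E:
            break
    else:
        logger.warning("slice did not converge within %d iterations", max_iter)
    return labels, (cx, cy, cl), n_iter


def segment_stack(
    stack: ImageStack,
    K: int = 1000,
    delta: float = 10.0,
    E: float = 1e-4,
    n: int = 3,
) -> SuperpixelMap:
    """Segment an (ROI) stack into superpixels, slice by slice.

    Slice 0 is seeded from the gradient-perturbed grid; each later slice
    inherits the converged centre positions of its predecessor. After
    convergence, per-slice connectivity is enforced and per-superpixel mean
    feature vectors are tabulated with globally unique superpixel ids.
    """
    if stack.n_slices == 0:
        raise StackValidationError("empty stack")
    if delta <= 0:
        raise StackValidationError("delta must be > 0")
    if E < 0 or K < 1 or n < 1 or n % 2 == 0:
        raise StackValidationError("invalid GSLIC parameters")
    h, w = stack.height, stack.width
    S = grid_step(h * w, K)

    data = stack.data
    lo, hi = data.min(), data.max()
    norm = (data - lo) * (100.0 / (hi - lo)) if hi > lo else np.zeros_like(data)

    label_slices: list[np.ndarray] = []
    feature_rows: list[np.ndarray] = []
    iterations: list[int] = []
    next_id = 0
    centers = None
    for z in range(stack.n_slices):
        lmap = norm[z]
        if z == 0:
            init = init_centers(lmap, S, n, z=0.0)
            cx = [c.x for c in init]
            cy = [c.y for c in init]
            cl = [c.l for c in init]
        else:
            # transmit the converged centres of slice z-1 to slice z
            cx, cy, cl = centers
        labels, centers, n_iter = _segment_slice(lmap, (cx, cy, cl), S, delta, E)
        iterations.append(n_iter)
        labels = enforce_connectivity(labels, S)
        labels, rows = _relabel_and_features(labels, lmap, z, next_id)
        next_id += len(rows)
        label_slices.append(labels)
        feature_rows.extend(rows)

    offset = getattr(stack, "offset", (0, 0))
    full_shape = getattr(stack, "full_shape", (h, w))
    return SuperpixelMap(
        labels=label_slices,
        features=np.array(feature_rows),
        S=S,
        params={"K": K, "delta": delta, "E": E, "n": n},
        offset=offset,
        full_shape=full_shape,
        iterations=iterations,
    )


def _relabel_and_features(labels, lmap, z, id_offset):
    """Compact labels to id_offset..id_offset+n-1 and tabulate mean features."""
    uniq, compact = np.unique(labels, return_inverse=True)
    compact = compact.reshape(labels.shape)
    n = len(uniq)
    counts = np.bincount(compact.ravel(), minlength=n).astype(float)
    h, w = lmap.shape
    xs = np.tile(np.arange(w, dtype=float), h)
    ys = np.repeat(np.arange(h, dtype=float), w)
    sum_x = np.bincount(compact.ravel(), weights=xs, minlength=n)
    sum_y = np.bincount(compact.ravel(), weights=ys, minlength=n)
    sum_l = np.bincount(compact.ravel(), weights=lmap.ravel(), minlength=n)
    rows = [
        np.array([sum_l[i] / counts[i], 0.0, 0.0, sum_x[i] / counts[i], sum_y[i] / counts[i], float(z)])
        for i in range(n)
    ]
    return compact + id_offset, rows


def enforce_connectivity(labels: np.ndarray, S: float) -> np.ndarray:
    """Make every superpixel 4-connected.

    For each label, the largest 4-connected component keeps the label;
    every other component (in particular orphans smaller than S²/4) is
    absorbed, smallest first, into the 4-adjacent neighbouring superpixel
    with the largest area. The label count never increases.
    """
    labels = labels.copy()
    h, w = labels.shape
    for _ in range(MAX_ITERATIONS):
        comp = measure.label(labels, connectivity=1, background=-1)
        n_comp = comp.max()
        if n_comp == len(np.unique(labels)):
            break
        comp_label = np.zeros(n_comp + 1, dtype=labels.dtype)
        comp_size = np.bincount(comp.ravel(), minlength=n_comp + 1)
        first = np.unique(comp, return_index=True)
        comp_label[first[0]] = labels.ravel()[first[1]]
        # keep the largest component of each label, collect the rest
        keep = {}
        for c in range(1, n_comp + 1):
            lab = comp_label[c]
            if lab not in keep or comp_size[c] > comp_size[keep[lab]]:
                keep[lab] = c
        orphans = [c for c in range(1, n_comp + 1) if keep[comp_label[c]] != c]
        if not orphans:
            break
        label_area = {
            lab: int(np.sum(labels == lab)) for lab in np.unique(labels)
        }
        orphans.sort(key=lambda c: comp_size[c])
        for c in orphans:
            mask = comp == c
            neighbours = _adjacent_labels(labels, mask)
            neighbours.discard(comp_label[c])
            if not neighbours:
                continue  # isolated label; nothing to merge into this pass
            target = max(neighbours, key=lambda lab: label_area.get(lab, 0))
            label_area[target] = label_area.get(target, 0) + int(mask.sum())
            label_area[comp_label[c]] -= int(mask.sum())
            labels[mask] = target
    return labels


def _adjacent_labels(labels: np.ndarray, mask: np.ndarray) -> set:
    """Labels 4-adjacent to the masked region (restricted to its bounding box)."""
    ys, xs = np.nonzero(mask)
    y0, y1 = ys.min(), ys.max()
    x0, x1 = xs.min(), xs.max()
    y0b, y1b = max(y0 - 1, 0), min(y1 + 2, labels.shape[0])
    x0b, x1b = max(x0 - 1, 0), min(x1 + 2, labels.shape[1])
    sub = labels[y0b:y1b, x0b:x1b]
    m = mask[y0b:y1b, x0b:x1b]
    out = set()
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        shifted = np.zeros_like(m)
        src = m[
            max(-dy, 0) : m.shape[0] - max(dy, 0),
            max(-dx, 0) : m.shape[1] - max(dx, 0),
        ]
        shifted[
            max(dy, 0) : m.shape[0] - max(-dy, 0),
            max(dx, 0) : m.shape[1] - max(-dx, 0),
        ] = src
        out.update(np.unique(sub[shifted & ~m]).tolist())
    return out
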