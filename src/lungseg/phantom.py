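"""Synthetic CT-like thorax phantoms with exact ground truth.

Each phantom stack emulates the contrast structure the segmentation
pipeline relies on: a bright elliptical body/pleural shell on a dark
extrathoracic background, two dark lung fields whose cross-sectional area
rises and then falls from the top to the bottom of the stack, an optional
trachea/bronchus disc between the lungs in the top third of the slices,
and optional nodules in one of three configurations (small benign disc,
larger malignant solitary nodule with a perturbed boundary, or a
wall-attached pleural nodule).

Two properties of real thorax CT are built in deliberately:

* lung parenchyma intensity is *close to* the extrathoracic background
  (both are essentially air), so the two cannot be told apart by grey
  value alone — only by spatial statistics;
* the body shell is far brighter than everything else.

The body ellipse fits inside the default ROI rectangle with a margin, so
the extrathoracic background forms a single connected frame around it.

Geometry is parameterised by frame size; the default 256×256×20 keeps
tests fast, and 512×512 works with the same fractions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stackio import ImageStack, MaskStack, StackValidationError
from .superpixels import default_roi_rect

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_phantom",
    "toy_labelmaps",
    "reference_sample_sets",
    "contrast_noise_sigma",
]

CATEGORIES = ("none", "benign", "malignant_spn", "pleural")


@dataclass
class PhantomConfig:
    """Parameters of a synthetic thorax stack.

    Intensity levels are in arbitrary CT-like units on [0, 255]; the
    defaults give a body–lung contrast of 140 and a lung–background gap
    of 50 (lung parenchyma is nearly as dark as the extrathoracic air).
    """

    width: int = 256
    height: int = 256
    n_slices: int = 20
    category: str = "none"
    background_level: float = 10.0
    lung_level: float = 60.0
    body_level: float = 200.0
    nodule_level: float = 130.0
    noise_sigma: float = 0.0
    trachea: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise StackValidationError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if self.noise_sigma < 0:
            raise StackValidationError("noise_sigma must be >= 0")
        if not (self.body_level > self.nodule_level > self.lung_level):
            raise StackValidationError(
                "intensity levels must satisfy body > nodule > lung"
            )
        if abs(self.lung_level - self.background_level) >= abs(
            self.body_level - self.lung_level
        ):
            raise StackValidationError(
                "lung level must be closer to background than to the body shell"
            )
        gap = min(
            self.body_level - self.nodule_level,
            self.nodule_level - self.lung_level,
            abs(self.lung_level - self.background_level),
        )
        if gap < 3.0 * self.noise_sigma:
            raise StackValidationError(
                f"intensity levels separated by {gap:.1f} < 3*noise_sigma "
                f"({3 * self.noise_sigma:.1f}); identification is ill-posed"
            )


@dataclass
class PhantomTruth:
    """Ground truth accompanying a phantom stack."""

    lung_masks: MaskStack            # {0, 1=left, 2=right}
    nodule_mask: MaskStack           # binary (label 1)
    trachea_mask: MaskStack          # binary (label 1)
    body_mask: np.ndarray = field(repr=False, default=None)  # bool, incl. lungs


def contrast_noise_sigma(config: PhantomConfig, fraction: float = 0.1) -> float:
    """Noise level as a fraction of the body–lung contrast."""
    return fraction * (config.body_level - config.lung_level)


def _ellipse(xx, yy, cx, cy, a, b):
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def _lung_scale(z: int, n_slices: int) -> float:
    """Cross-section scale factor: rises to mid-stack then falls."""
    return 0.55 + 0.45 * math.sin(math.pi * (z + 0.5) / n_slices)


def generate_phantom(config: PhantomConfig) -> tuple[ImageStack, PhantomTruth]:
    """Render a phantom stack and its ground truth, deterministically."""
    W, H, Z = config.width, config.height, config.n_slices
    x0, y0, x1, y1 = default_roi_rect(W, H)
    cx, cy = (x0 + x1) / 2.0, (y0 + y1) / 2.0
    margin = max(6, round(0.047 * W))
    body_a, body_b = (x1 - x0) / 2.0 - margin, (y1 - y0) / 2.0 - margin
    lung_dx = 0.12 * W           # lung centre offset from the midline
    lung_a, lung_b = 0.085 * W, 0.16 * H
    trachea_r = 0.02 * W
    n_trachea = math.ceil(Z / 3)

    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    rng = np.random.default_rng(config.rng_seed)

    images = np.empty((Z, H, W))
    lungs = np.zeros((Z, H, W), dtype=np.uint8)
    nodules = np.zeros((Z, H, W), dtype=np.uint8)
    trachea = np.zeros((Z, H, W), dtype=np.uint8)
    body_all = np.zeros((Z, H, W), dtype=bool)

    for z in range(Z):
        f = _lung_scale(z, Z)
        body = _ellipse(xx, yy, cx, cy, body_a, body_b)
        left = _ellipse(xx, yy, cx - lung_dx, cy, lung_a * f, lung_b * f)
        right = _ellipse(xx, yy, cx + lung_dx, cy, lung_a * f, lung_b * f)

        img = np.full((H, W), config.background_level)
        img[body] = config.body_level
        img[left | right] = config.lung_level

        if config.trachea and z < n_trachea:
            tr = _ellipse(xx, yy, cx, cy, trachea_r, trachea_r)
            img[tr] = config.lung_level
            trachea[z][tr] = 1

        nod = _nodule_mask(config, z, Z, xx, yy, cx, cy, lung_dx, lung_a, lung_b, f, body)
        if nod is not None:
            img[nod] = config.nodule_level
            nodules[z][nod] = 1

        lungs[z][left] = 1
        lungs[z][right] = 2
        body_all[z] = body
        images[z] = img

    if config.noise_sigma > 0:
        images = images + rng.normal(0.0, config.noise_sigma, images.shape)
        np.clip(images, 0.0, 255.0, out=images)

    truth = PhantomTruth(
        lung_masks=MaskStack(lungs),
        nodule_mask=MaskStack(nodules),
        trachea_mask=MaskStack(trachea),
        body_mask=body_all,
    )
    return ImageStack(images), truth


def _nodule_mask(config, z, Z, xx, yy, cx, cy, lung_dx, lung_a, lung_b, f, body):
    """Nodule footprint on slice z, or None. All nodules sit in/on the right lung."""
    W, H = config.width, config.height
    rx, ry = cx + lung_dx, cy
    mid = Z // 2
    if config.category == "benign":
        if abs(z - mid) > 1:
            return None
        lung = _ellipse(xx, yy, rx, ry, lung_a * f, lung_b * f)
        disc = _ellipse(xx, yy, rx + 0.03 * W, ry - 0.04 * H, 0.02 * W, 0.02 * W)
        return disc & lung
    if config.category == "malignant_spn":
        if abs(z - mid) > 2:
            return None
        lung = _ellipse(xx, yy, rx, ry, lung_a * f, lung_b * f)
        ncx, ncy = rx - 0.02 * W, ry + 0.05 * H
        theta = np.arctan2(yy - ncy, xx - ncx)
        r = np.hypot(xx - ncx, yy - ncy)
        boundary = 0.035 * W * (1.0 + 0.25 * np.sin(5.0 * theta))
        return (r <= boundary) & lung
    if config.category == "pleural":
        if abs(z - mid) > 1:
            return None
        # disc centred on the lateral lung boundary, clipped to the body:
        # part lies in the lung, part in the pleural wall
        disc = _ellipse(xx, yy, rx + lung_a * f, ry, 0.03 * W, 0.03 * W)
        return disc & body
    return None


# ---------------------------------------------------------------------------
# small fixtures with hand-checkable metric values

_TOY_CASES = {
    # two equal partitions
    "identical": (
        np.array([[1, 1], [2, 2]]),
        np.array([[1, 1], [2, 2]]),
    ),
    # statistically independent labelings: VoI = 2 bits
    "independent": (
        np.array([[1, 1], [2, 2]]),
        np.array([[1, 2], [1, 2]]),
    ),
    # binary masks with |A ∩ B| = 2, |A ∪ B| = 4: Jaccard = 0.5
    "half_overlap": (
        np.array([[1, 1], [1, 0]]),
        np.array([[0, 1], [1, 1]]),
    ),
    # half the pixel pairs agree: PRI = 0.5
    "agree_half": (
        np.array([[1, 1], [2, 2]]),
        np.array([[1, 1], [1, 2]]),
    ),
}


def toy_labelmaps(case_id: str) -> tuple[np.ndarray, np.ndarray]:
    """Paired ≤5×5 segmentations with hand-checkable metric values."""
    try:
        a, b = _TOY_CASES[case_id]
    except KeyError:
        raise KeyError(
            f"unknown case {case_id!r}; known: {sorted(_TOY_CASES)}"
        ) from None
    return a.copy(), b.copy()


# ---------------------------------------------------------------------------
# ground-truth-derived sample sets for exercising the identification rules

def reference_sample_sets(
    stack: ImageStack,
    truth: PhantomTruth,
    rect: tuple[int, int, int, int] | None = None,
    block: int = 8,
) -> list[np.ndarray]:
    """Build the four superpixel-like sample sets from ground truth.

    Partitions the ROI pixels of each slice into the four true regions
    (body shell, extrathoracic background, left lung, right lung; trachea
    pixels excluded), tiles each region with ``block``×``block`` cells and
    averages each non-empty cell into one [l, a, b, x, y, z] sample with
    ``l`` min–max scaled to [0, 100] over the ROI — the same embedding the
    superpixel stage produces. Returned in the order
    [body, background, left lung, right lung].
    """
    if rect is None:
        rect = default_roi_rect(stack.width, stack.height)
    x0, y0, x1, y1 = rect
    roi = stack.data[:, y0:y1, x0:x1]
    lo, hi = roi.min(), roi.max()
    scale = 100.0 / (hi - lo) if hi > lo else 0.0
    lungs = truth.lung_masks.data[:, y0:y1, x0:x1]
    body = truth.body_mask[:, y0:y1, x0:x1]
    trach = truth.trachea_mask.data[:, y0:y1, x0:x1] > 0
    h, w = roi.shape[1:]

    regions = [
        body & (lungs == 0) & ~trach,            # pleural/body shell
        ~body,                                    # extrathoracic background
        lungs == 1,
        lungs == 2,
    ]
    sets = []
    for region in regions:
        samples = []
        for z in range(roi.shape[0]):
            mask = region[z]
            for by in range(0, h, block):
                for bx in range(0, w, block):
                    cell = mask[by : by + block, bx : bx + block]
                    if not cell.any():
                        continue
                    ys, xs = np.nonzero(cell)
                    vals = roi[z, by : by + block, bx : bx + block][cell]
                    samples.append(
                        [
                            (vals.mean() - lo) * scale,
                            0.0,
                            0.0,
                            float(xs.mean() + bx),
                            float(ys.mean() + by),
                            float(z),
                        ]
                    )
        sets.append(np.array(samples))
    return sets
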