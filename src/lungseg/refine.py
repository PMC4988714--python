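"""Coarse-mask refinement: trachea removal and contour smoothing.

The coarse masks from the identification stage still contain the
trachea/bronchus (dark, lung-like, so it clusters with the lungs) and
ragged superpixel boundaries. Refinement runs per slice:

1. binarize (adaptive two-class threshold),
2. take the minimum bounding rectangle of the foreground,
3. pick one seed per side with the left–right scan (LRS) rule,
4. region-grow from the seeds (keep only the 4-connected components
   containing a seed — the lungs; disconnected trachea and noise drop out),
5. smooth the contour with morphological closing then opening.

The LRS rule scans rectangle columns inward from the left and from the
right; the first column holding a run of more than 5 consecutive
foreground pixels in y yields a seed at the run's third pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

from .stackio import MaskStack, StackValidationError

__all__ = [
    "SeedPair",
    "binarize",
    "min_bounding_rect",
    "lrs_seeds",
    "region_grow",
    "smooth_mask",
    "refine_stack",
]

logger = logging.getLogger(__name__)

FOREGROUND = 255
MIN_RUN = 6  # "more than 5 consecutive points"


@dataclass
class SeedPair:
    """Left/right region-growing seeds, (x, y), on foreground pixels."""

    left: tuple[int, int] | None
    right: tuple[int, int] | None
    z: int = 0

    @property
    def any(self) -> bool:
        return self.left is not None or self.right is not None


def binarize(slice_: np.ndarray) -> np.ndarray:
    """Adaptive two-class threshold to {0, 255}; idempotent on binary input.

    The threshold maximises the between-class variance of the slice
    histogram (Otsu). A constant slice has no two classes and maps to
    all-background.
    """
    slice_ = np.asarray(slice_, dtype=float)
    if np.all(slice_ == slice_.flat[0]):
        logger.info("constant slice; binarized to all-background")
        return np.zeros(slice_.shape, dtype=np.uint8)
    thr = threshold_otsu(slice_)
    return np.where(slice_ > thr, FOREGROUND, 0).astype(np.uint8)


def min_bounding_rect(binary: np.ndarray) -> tuple[int, int, int, int]:
    """Tightest axis-aligned rectangle (x0, y0, x1, y1), inclusive corners."""
    ys, xs = np.nonzero(binary)
    if ys.size == 0:
        raise StackValidationError("no foreground pixels; bounding rectangle undefined")
    return int(xs.min()), int(ys.min()), int(xs.max()), int(ys.max())


def _scan_column(column: np.ndarray) -> int | None:
    """Ordinate of the 3rd pixel of the first run of ≥ MIN_RUN, else None."""
    run_start = run_len = 0
    for i, v in enumerate(column):
        if v:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len == MIN_RUN:
                return run_start + 2
        else:
            run_len = 0
    return None


def lrs_seeds(binary: np.ndarray, rect: tuple[int, int, int, int], z: int = 0) -> SeedPair:
    """Left–right scan for region-growing seeds inside the bounding rect."""
    x0, y0, x1, y1 = rect
    fg = np.asarray(binary) > 0
    left = right = None
    for x in range(x0, x1 + 1):
        row = _scan_column(fg[y0 : y1 + 1, x])
        if row is not None:
            left = (x, y0 + row)
            break
    for x in range(x1, x0 - 1, -1):
        row = _scan_column(fg[y0 : y1 + 1, x])
        if row is not None:
            right = (x, y0 + row)
            break
    if left is None and right is None:
        logger.info("no qualifying foreground run on either side; slice flagged no-lung")
    return SeedPair(left=left, right=right, z=z)


def region_grow(binary: np.ndarray, seeds: SeedPair) -> np.ndarray:
    """Union of the 4-connected foreground components containing the seeds."""
    fg = np.asarray(binary) > 0
    comp = measure.label(fg, connectivity=1)
    keep = set()
    for seed in (seeds.left, seeds.right):
        if seed is None:
            continue
        x, y = seed
        if not fg[y, x]:
            raise StackValidationError(f"seed {seed} is not on foreground")
        keep.add(comp[y, x])
    out = np.isin(comp, sorted(keep)) if keep else np.zeros_like(fg)
    return np.where(out, FOREGROUND, 0).astype(np.uint8)


def smooth_mask(binary: np.ndarray, radius: int = 2) -> np.ndarray:
    """Morphological closing then opening with a disc of the given radius."""
    if radius < 1:
        raise StackValidationError("smoothing radius must be >= 1")
    fg = np.asarray(binary) > 0
    selem = morphology.disk(radius)
    out = morphology.opening(morphology.closing(fg, selem), selem)
    return np.where(out, FOREGROUND, 0).astype(np.uint8)


def refine_stack(coarse: MaskStack, radius: int | None = None) -> MaskStack:
    """Apply the five refinement steps per slice and relabel left/right.

    ``radius`` defaults to 2 px at 512×512, scaled with frame width.
    Slices with no qualifying seed produce empty masks (logged).
    """
    if not isinstance(coarse, MaskStack):
        coarse = MaskStack(np.asarray(coarse))
    if radius is None:
        radius = max(1, round(2 * coarse.width / 512))
    out = np.zeros_like(coarse.data)
    for z, cslice in enumerate(coarse.data):
        binary = binarize(cslice)
        if not binary.any():
            continue
        rect = min_bounding_rect(binary)
        seeds = lrs_seeds(binary, rect, z=z)
        if not seeds.any:
            logger.info("slice %d: no seeds; empty mask", z)
            continue
        logger.debug("slice %d seeds: left=%s right=%s", z, seeds.left, seeds.right)
        grown = region_grow(binary, seeds)
        smooth = smooth_mask(grown, radius) > 0
        out[z] = _relabel_sides(smooth, cslice)
    return MaskStack(out)


def _relabel_sides(final: np.ndarray, coarse_slice: np.ndarray) -> np.ndarray:
    """Give each final component the majority left/right label of the coarse mask."""
    comp = measure.label(final, connectivity=1)
    out = np.zeros(final.shape, dtype=np.uint8)
    for c in range(1, comp.max() + 1):
        mask = comp == c
        labels = coarse_slice[mask]
        labels = labels[labels > 0]
        if labels.size == 0:
            logger.info("final component with no coarse overlap; labelled left")
            out[mask] = 1
        else:
            counts = np.bincount(labels, minlength=3)
            out[mask] = 1 if counts[1] >= counts[2] else 2
    return out
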