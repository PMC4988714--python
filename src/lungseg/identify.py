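"""Cluster identification: which sample set is which anatomical region.

After clustering, the superpixels fall into four sample sets covering the
pleural/body tissue, the extrathoracic area, and the left and right lung
parenchyma. Two per-set statistics decide which is which:

* the mean grey value φ(X) = (1/n) Σ sqrt(a₁² + a₂² + a₃²) over the
  members' (l, a, b) — highest for the bright pleural tissue;
* the coordinate variance ξ²(X) = (1/n) Σ [(x−x₀)² + (y−y₀)²] about the
  set centroid — highest for the extrathoracic area, whose superpixels
  are scattered around the frame, while lung coordinates are
  concentrated.

The remaining two sets are the lungs; the one with the smaller centroid
x is the left lung (image coordinates). Ties are broken by lower cluster
index and logged as degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .stackio import MaskStack, StackValidationError

__all__ = [
    "SampleSetStats",
    "RegionLabeling",
    "mean_gray",
    "centroid_and_variance",
    "set_stats",
    "identify_regions",
    "assemble_masks",
]

logger = logging.getLogger(__name__)

ROLES = ("pleural", "extrathoracic", "left_lung", "right_lung")


@dataclass
class SampleSetStats:
    mean_gray: float
    centroid: tuple[float, float]
    coord_var: float
    n: int


@dataclass
class RegionLabeling:
    """Bijection between the four cluster indices and the four roles."""

    pleural: int
    extrathoracic: int
    left_lung: int
    right_lung: int

    def role_of(self, cluster: int) -> str:
        for role in ROLES:
            if getattr(self, role) == cluster:
                return role
        raise KeyError(cluster)


def mean_gray(members: np.ndarray) -> float:
    """φ(X): mean (l, a, b) norm over the set members."""
    members = np.asarray(members, dtype=float)
    if members.ndim != 2 or members.shape[0] == 0:
        raise StackValidationError("sample set must be a non-empty (n, 6) table")
    return float(np.mean(np.linalg.norm(members[:, :3], axis=1)))


def centroid_and_variance(members: np.ndarray) -> tuple[tuple[float, float], float]:
    """Centroid (x₀, y₀) and coordinate variance ξ² of the set."""
    members = np.asarray(members, dtype=float)
    if members.ndim != 2 or members.shape[0] == 0:
        raise StackValidationError("sample set must be a non-empty (n, 6) table")
    x0 = float(members[:, 3].mean())
    y0 = float(members[:, 4].mean())
    var = float(np.mean((members[:, 3] - x0) ** 2 + (members[:, 4] - y0) ** 2))
    return (x0, y0), var


def set_stats(members: np.ndarray) -> SampleSetStats:
    (x0, y0), var = centroid_and_variance(members)
    return SampleSetStats(mean_gray(members), (x0, y0), var, int(len(members)))


def identify_regions(sets: list[np.ndarray]) -> RegionLabeling:
    """Assign the four roles to four sample sets.

    pleural = argmax mean grey; extrathoracic = argmax coordinate variance
    among the remaining three; the last two are the lungs, ordered by
    centroid x.
    """
    if len(sets) != 4:
        raise StackValidationError(f"exactly 4 sample sets required, got {len(sets)}")
    stats = [set_stats(s) for s in sets]

    grays = [st.mean_gray for st in stats]
    pleural = int(np.argmax(grays))
    if grays.count(max(grays)) > 1:
        logger.warning("degenerate mean-grey tie; lowest cluster index wins")

    rest = [i for i in range(4) if i != pleural]
    variances = [stats[i].coord_var for i in rest]
    extrathoracic = rest[int(np.argmax(variances))]
    if variances.count(max(variances)) > 1:
        logger.warning("degenerate coordinate-variance tie; lowest cluster index wins")

    lungs = [i for i in rest if i != extrathoracic]
    xs = [stats[i].centroid[0] for i in lungs]
    if xs[0] == xs[1]:
        logger.warning("degenerate lung centroid tie; lower cluster index is left")
    left, right = (lungs[0], lungs[1]) if xs[0] <= xs[1] else (lungs[1], lungs[0])
    return RegionLabeling(
        pleural=pleural, extrathoracic=extrathoracic, left_lung=left, right_lung=right
    )


def assemble_masks(lung_sets, spmap, geometry=None) -> MaskStack:
    """Paint the lung superpixels into full-frame coarse masks.

    ``lung_sets`` is (left ids, right ids); every pixel of a left-set
    superpixel becomes label 1 and of a right-set superpixel label 2,
    re-embedded into the full frame via the ROI offset; slices ascend in z.
    """
    left_ids, right_ids = lung_sets
    if geometry is None:
        geometry = (len(spmap.labels), *spmap.full_shape)
    n_slices, H, W = geometry
    x_off, y_off = spmap.offset
    value = np.zeros(spmap.n_superpixels, dtype=np.uint8)
    for sid in np.asarray(left_ids, dtype=int):
        value[sid] = 1
    for sid in np.asarray(right_ids, dtype=int):
        value[sid] = 2
    z_of = spmap.features[:, 5]
    for sid in np.concatenate([np.asarray(left_ids, int), np.asarray(right_ids, int)]):
        if not (0 <= z_of[sid] < n_slices):
            raise StackValidationError(f"superpixel {sid} has slice {z_of[sid]} outside the stack")
    out = np.zeros((n_slices, H, W), dtype=np.uint8)
    for z, labels in enumerate(spmap.labels):
        painted = value[labels]
        h, w = labels.shape
        out[z, y_off : y_off + h, x_off : x_off + w] = painted
    return MaskStack(out)
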