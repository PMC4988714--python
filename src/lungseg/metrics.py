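"""Segmentation agreement measures: PRI, VoI, Jaccard, volume overlap.

All measures compare a reference label map/stack ``Ss`` against a test
one ``Sr`` of identical geometry.

* PRI (probabilistic Rand index): the fraction of unordered pixel pairs
  on which the two segmentations agree — same label in both, or
  different label in both. 1 is perfect. Computed from the label
  co-occurrence table in O(M + K·N) rather than enumerating the
  O(M²) pairs.
* VoI (variation of information): H(Ss) + H(Sr) − 2·I(Ss, Sr) over the
  empirical label distributions, in bits. 0 means the partitions are
  identical up to renaming.
* Jaccard: |Ss ∩ Sr| / |Ss ∪ Sr| for binary masks; the volumetric
  percentage form ("volume pixel overlap ratio") pools all slices.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import sparse

from .stackio import StackValidationError

__all__ = ["pri", "voi", "jaccard", "volume_overlap", "contingency"]

logger = logging.getLogger(__name__)


def _flatten_pair(ss, sr) -> tuple[np.ndarray, np.ndarray]:
    ss = np.asarray(getattr(ss, "data", ss))
    sr = np.asarray(getattr(sr, "data", sr))
    if ss.shape != sr.shape:
        raise StackValidationError(f"geometry mismatch: {ss.shape} vs {sr.shape}")
    return ss.ravel(), sr.ravel()


def contingency(ss, sr) -> np.ndarray:
    """Label co-occurrence counts n_kn between two label maps."""
    a, b = _flatten_pair(ss, sr)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    return (
        sparse.coo_matrix((np.ones(a.size), (ai, bi)))
        .toarray()
        .astype(np.int64)
    )


def pri(ss, sr) -> float:
    """Probabilistic Rand index over all unordered pixel pairs."""
    a, _ = _flatten_pair(ss, sr)
    M = a.size
    if M < 2:
        raise StackValidationError("PRI needs at least two pixels")
    n = contingency(ss, sr)

    def pairs(x):
        return float(np.sum(x * (x - 1))) / 2.0

    total = M * (M - 1) / 2.0
    same_both = pairs(n)
    same_ref = pairs(n.sum(axis=1))
    same_test = pairs(n.sum(axis=0))
    diff_both = total - same_ref - same_test + same_both
    return (same_both + diff_both) / total


def voi(ss, sr) -> float:
    """Variation of information in bits."""
    n = contingency(ss, sr)
    M = n.sum()
    p_kn = n / M
    p_k = p_kn.sum(axis=1)
    p_n = p_kn.sum(axis=0)

    def entropy(p):
        p = p[p > 0]
        return float(-np.sum(p * np.log2(p)))

    nz = p_kn > 0
    mutual = float(
        np.sum(p_kn[nz] * np.log2(p_kn[nz] / np.outer(p_k, p_n)[nz]))
    )
    value = entropy(p_k) + entropy(p_n) - 2.0 * mutual
    return max(value, 0.0)  # clip negative rounding residue


def jaccard(ss, sr) -> float:
    """|Ss ∩ Sr| / |Ss ∪ Sr| on binary (foreground) masks."""
    a, b = _flatten_pair(ss, sr)
    fa, fb = a > 0, b > 0
    union = np.sum(fa | fb)
    if union == 0:
        logger.info("both masks empty; Jaccard defined as 1")
        return 1.0
    return float(np.sum(fa & fb)) / float(union)


def volume_overlap(ss, sr) -> float:
    """Volumetric Jaccard over the pooled voxel sets, as a percentage."""
    return 100.0 * jaccard(ss, sr)
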