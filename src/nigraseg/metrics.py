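"""Segmentation and cohort evaluation metrics.

All overlap metrics operate on :class:`~nigraseg.volume.BinaryMask` pairs on
one grid. Degenerate-case conventions: perfect agreement between two empty
masks scores 1 (configurable), a 0/0 precision or sensitivity with any
non-empty operand scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .volume import BinaryMask

#: cap applied when two histograms share no support (distance would be +inf)
BHATTACHARYYA_CAP = float(np.log(1e6))


@dataclass
class MetricReport:
    """Dice / precision / sensitivity for one segmentation, each in [0, 1]."""

    dice: float
    precision: float
    sensitivity: float
    accuracy: float | None = None


def _check_same_grid(a: BinaryMask, b: BinaryMask) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")


def dice(a: BinaryMask, b: BinaryMask, empty_value: float = 1.0) -> float:
    """Dice overlap 2|a∩b| / (|a|+|b|); two empty masks score ``empty_value``."""
    _check_same_grid(a, b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return empty_value
    inter = int(np.logical_and(a.data, b.data).sum())
    return 2.0 * inter / (na + nb)


def precision_sensitivity(pred: BinaryMask, truth: BinaryMask) -> MetricReport:
    """Voxelwise precision TP/(TP+FP) and sensitivity TP/(TP+FN).

    A 0/0 ratio is 1 when both masks are empty (vacuously perfect) and 0
    otherwise.
    """
    _check_same_grid(pred, truth)
    tp = int(np.logical_and(pred.data, truth.data).sum())
    fp = pred.count() - tp
    fn = truth.count() - tp
    both_empty = pred.count() == 0 and truth.count() == 0
    precision = tp / (tp + fp) if tp + fp else (1.0 if both_empty else 0.0)
    sensitivity = tp / (tp + fn) if tp + fn else (1.0 if both_empty else 0.0)
    return MetricReport(dice=dice(pred, truth), precision=precision,
                        sensitivity=sensitivity)


def inter_rater_r(a1: BinaryMask, a2: BinaryMask) -> float:
    """Inter-rater reliability r = |A1 ⊙ A2| / |A1|.

    The fraction of the reference annotation ``a1`` that the second rater
    ``a2`` also labelled. |·| counts foreground voxels, so r is the
    intersection-over-reference ratio; note r is *not* symmetric.
    """
    _check_same_grid(a1, a2)
    n1 = a1.count()
    if n1 == 0:
        raise ValueError("reference annotation a1 is empty")
    inter = int(np.logical_and(a1.data, a2.data).sum())
    return inter / n1


def bhattacharyya_distance(x1, x2, bins: int = 64) -> float:
    """Bhattacharyya distance between two intensity samples.

    Histograms with ``bins`` equal-width bins are built over the union of the
    two sample ranges, normalized to probability mass, and the distance is
    ``-ln Σ_i sqrt(p_i q_i)``. Zero-mass product bins contribute nothing. A
    distance that would be infinite (disjoint supports) is capped at
    ``BHATTACHARYYA_CAP`` with a warning.
    """
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.size == 0 or x2.size == 0:
        raise ValueError("intensity samples must be non-empty")
    lo = min(x1.min(), x2.min())
    hi = max(x1.max(), x2.max())
    if hi == lo:  # all values identical -> identical degenerate histograms
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    p = np.histogram(x1, bins=edges)[0] / x1.size
    q = np.histogram(x2, bins=edges)[0] / x2.size
    bc = float(np.sqrt(p * q).sum())
    if bc <= np.exp(-BHATTACHARYYA_CAP):
        warnings.warn("histograms share no support; distance capped")
        return BHATTACHARYYA_CAP
    return -float(np.log(bc))


def volume_change_ratio(v_first: float, v_second: float) -> float:
    """Longitudinal change ratio R = second-visit / first-visit.

    Serves both segmentation-volume ratios and clinical-score ratios (R_U).
    """
    if v_first <= 0:
        raise ValueError("first-visit value must be positive")
    return v_second / v_first


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation coefficient with its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("series must have nonzero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
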