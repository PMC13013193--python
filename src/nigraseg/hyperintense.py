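"""Hyperintense-region estimation and threshold-based PD identification.

The radiological clue proxied here is nigrosome-1: on neuromelanin-sensitive
MRI the healthy substantia nigra contains a hyperintense region that shrinks
in Parkinson's disease. The hyperintensity cut-off is referenced to the
midbrain background,

    t = mu + alpha * sigma   (alpha = 1.5),

where mu and sigma are the mean and population standard deviation of the
intensities in the midbrain excluding the SN. The hyperintense region is
the set of SN voxels strictly brighter than t; a case whose hyperintense
area (in the axial slice with the largest SN area, mm^2) or volume (voxel
count) falls strictly below a criterion is identified as PD. Sweeping the
criterion yields the ROC curve; its area equals the probability that a
random PD case scores below a random HC case (ties counted half).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .ttd import mean_std_over_passes
from .volume import BinaryMask, ImageVolume

#: multiplier from the hyperintensity threshold definition
DEFAULT_ALPHA = 1.5
#: recommended hyperintense-area criterion for axial-slice identification, mm^2
AREA_CRITERION_MM2 = 61.2
#: hyperintense-volume criterion for volumetric identification, voxels
VOLUME_CRITERION_VOXELS = 400.0


@dataclass
class HyperintenseResult:
    """Hyperintensity threshold, background statistics and the region mask."""

    threshold_t: float
    region: BinaryMask
    mu: float
    sigma: float
    alpha: float


@dataclass
class IdentificationResult:
    """Per-case identification: score, criterion and the PD call.

    ``positive`` (PD) iff score < criterion, strictly.
    """

    score: float
    criterion: float
    positive: bool
    mode: str


def segment_midbrain(t1: ImageVolume, model2d, n_passes: int = 8,
                     seed: int = 0, threshold: float = 0.5) -> BinaryMask:
    """Segment the midbrain from a (normalized) T1-like volume slice-wise.

    Axial slices are pushed through the 2D network as one batch per pass;
    test-time-dropout passes are averaged and the mean probability is
    binarized and restacked into a 3D mask on the input grid.
    """
    data = t1.data.astype(np.float32)
    slices = np.moveaxis(data, 2, 0)[:, None]  # (D, 1, H, W)
    if model2d.cfg.dropout_rate == 0 or n_passes == 1:
        with ad.no_grad():
            prob = model2d(slices).data[:, 0]
    else:
        rng = np.random.default_rng(seed)
        acc = []
        with ad.no_grad():
            for _ in range(n_passes):
                acc.append(model2d(slices, dropout_on=True,
                                   rng=rng).data[:, 0])
        prob = mean_std_over_passes(np.stack(acc))[0]
    mask = np.moveaxis(prob > threshold, 0, 2).astype(np.uint8)
    return BinaryMask(mask, t1.affine)


def make_slice_cases(volumes, per_subject: int = 12, seed: int = 0,
                     foreground_fraction: float = 0.75):
    """Build 2D training cases from (T1 volume, midbrain mask) pairs.

    Samples ``per_subject`` axial slices per subject, mostly slices that
    contain midbrain (so the network sees the target) with a minority of
    empty slices (so it learns to stay silent on background). Returns
    ``(slice, None, mask-slice)`` triples compatible with the trainer.
    """
    from .training import normalize_intensity

    rng = np.random.default_rng(seed)
    cases = []
    for t1, midbrain in volumes:
        data = normalize_intensity(t1).data.astype(np.float32)
        counts = midbrain.data.sum(axis=(0, 1))
        fg = np.flatnonzero(counts > 0)
        bg = np.flatnonzero(counts == 0)
        n_fg = min(len(fg), max(1, round(per_subject
                                         * foreground_fraction)))
        n_bg = min(len(bg), per_subject - n_fg)
        chosen = np.concatenate([
            rng.choice(fg, size=n_fg, replace=False) if n_fg else [],
            rng.choice(bg, size=n_bg, replace=False) if n_bg else [],
        ]).astype(int)
        for k in chosen:
            cases.append((data[:, :, k], None, midbrain.data[:, :, k]))
    return cases


def hyperintense_threshold(nm: ImageVolume, midbrain: BinaryMask,
                           sn: BinaryMask, alpha: float = DEFAULT_ALPHA
                           ) -> tuple[float, float, float]:
    """Intensity cut-off t = mu + alpha*sigma over midbrain-minus-SN voxels.

    Returns ``(t, mu, sigma)``; sigma is the population standard deviation.
    """
    if nm.shape != midbrain.shape or nm.shape != sn.shape:
        raise ValueError("volume and mask grids differ")
    background = np.logical_and(midbrain.data, np.logical_not(sn.data))
    if not background.any():
        raise ValueError("midbrain-minus-SN background is empty")
    values = nm.data[background].astype(np.float64)
    mu = float(values.mean())
    sigma = float(values.std())  # population convention
    return mu + alpha * sigma, mu, sigma


def hyperintense_region(nm: ImageVolume, domain: BinaryMask,
                        t: float) -> BinaryMask:
    """Voxels of ``domain`` with intensity strictly greater than ``t``."""
    if nm.shape != domain.shape:
        raise ValueError("volume and domain grids differ")
    region = np.logical_and(domain.data, nm.data > t).astype(np.uint8)
    return BinaryMask(region, nm.affine)


def estimate_hyperintense(nm: ImageVolume, midbrain: BinaryMask,
                          sn: BinaryMask, alpha: float = DEFAULT_ALPHA
                          ) -> HyperintenseResult:
    """Full hyperintensity estimate with the SN as the region domain."""
    t, mu, sigma = hyperintense_threshold(nm, midbrain, sn, alpha)
    return HyperintenseResult(threshold_t=t,
                              region=hyperintense_region(nm, sn, t),
                              mu=mu, sigma=sigma, alpha=alpha)


def largest_sn_axial_slice(sn: BinaryMask) -> int:
    """Index of the axial slice with the largest SN area (ties -> smallest)."""
    counts = sn.data.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise ValueError("SN mask is empty")
    return int(np.argmax(counts))


def identify_case(hyper: BinaryMask, sn: BinaryMask, spacing,
                  mode: str = "volume",
                  criterion: float | None = None) -> IdentificationResult:
    """Identify a case as PD from its hyperintense region size.

    ``mode='area'``: hyperintense pixel count in the largest-SN axial slice
    times the in-plane pixel area (mm^2), default criterion 61.2 mm^2.
    ``mode='volume'``: total hyperintense voxel count, default criterion
    400 voxels. Positive (PD) iff score < criterion, strictly.
    """
    if hyper.shape != sn.shape:
        raise ValueError("mask grids differ")
    if mode == "area":
        criterion = AREA_CRITERION_MM2 if criterion is None else criterion
        k = largest_sn_axial_slice(sn)
        score = float(hyper.data[:, :, k].sum()) * float(spacing[0]) \
            * float(spacing[1])
    elif mode == "volume":
        criterion = VOLUME_CRITERION_VOXELS if criterion is None \
            else criterion
        score = float(hyper.data.sum())
    else:
        raise ValueError(f"unknown identification mode {mode!r}")
    return IdentificationResult(score=score, criterion=float(criterion),
                                positive=bool(score < criterion), mode=mode)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve and AUC for smaller-score-is-PD identification.

    ``labels`` are truth (True/1 = PD). The criterion sweeps over all
    distinct scores (positive iff score < criterion); the returned curve is
    an array of (FPR, TPR) rows including the (0,0) and (1,1) endpoints.
    The AUC is the tie-aware pair-ordering probability
    P(score_PD < score_HC) + 0.5 P(equal), identical to the trapezoidal
    area under the swept curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    points = []
    for c in thresholds:
        pred = scores < c
        tpr = (pred & labels).sum() / n_pos
        fpr = (pred & ~labels).sum() / n_neg
        points.append((fpr, tpr))
    points = np.unique(np.array([(0.0, 0.0)] + points + [(1.0, 1.0)]),
                       axis=0)
    pos = scores[labels]
    neg = scores[~labels]
    wins = (pos[:, None] < neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    auc = (wins + 0.5 * ties) / (n_pos * n_neg)
    return points, float(auc)


def confusion_stats(predictions, truths) -> dict:
    """Accuracy, precision and sensitivity with PD as the positive class.

    ``predictions`` and ``truths`` are boolean sequences (True = PD).
    """
    predictions = np.asarray(predictions, dtype=bool)
    truths = np.asarray(truths, dtype=bool)
    if predictions.shape != truths.shape or predictions.size == 0:
        raise ValueError("predictions and truths must be equal-length and "
                         "non-empty")
    tp = int((predictions & truths).sum())
    fp = int((predictions & ~truths).sum())
    fn = int((~predictions & truths).sum())
    tn = int((~predictions & ~truths).sum())
    n = tp + fp + fn + tn
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": (tp + tn) / n,
        "precision": tp / (tp + fp) if tp + fp else 0.0,
        "sensitivity": tp / (tp + fn) if tp + fn else 0.0,
    }
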