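"""Test-time-dropout (TTD) inference: mean prediction and uncertainty.

Keeping dropout active at inference turns the network into an approximate
Bayesian predictor: N stochastic passes yield a voxelwise mean probability
map S and a population-standard-deviation uncertainty map U,

    s_ijk = (1/N) sum_l s_ijk^(l),
    u_ijk = sqrt((1/N) sum_l (s_ijk^(l) - s_ijk)^2),

with N = 30 by default. U is bounded by 0.5 (the largest possible standard
deviation of values in [0, 1]) and is high where the passes disagree —
typically on vague anatomical boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import autodiff as ad
from .registration import ROIBox
from .volume import BinaryMask

#: number of stochastic passes used by default
DEFAULT_PASSES = 30


@dataclass
class TTDResult:
    """Mean probability map, uncertainty map and the number of passes."""

    prob: np.ndarray
    uncertainty: np.ndarray
    n: int

    def __post_init__(self) -> None:
        if self.prob.shape != self.uncertainty.shape:
            raise ValueError("probability and uncertainty grids differ")
        if self.prob.min() < 0 or self.prob.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.uncertainty.min() < -1e-6 or self.uncertainty.max() > 0.5 + 1e-6:
            raise ValueError("uncertainty must lie in [0, 0.5]")


def mean_std_over_passes(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise mean and population std over a (N, ...) stack of passes."""
    stack = np.asarray(stack, dtype=np.float64)
    prob = stack.mean(axis=0)
    unc = np.sqrt(np.mean((stack - prob) ** 2, axis=0))
    return prob.astype(np.float32), unc.astype(np.float32)


def ttd_predict(model, image: np.ndarray, sppm: np.ndarray | None = None,
                n: int = DEFAULT_PASSES, seed: int = 0) -> TTDResult:
    """Aggregate ``n`` dropout-on passes into mean and uncertainty maps.

    With dropout rate zero the passes are identical, so a single
    deterministic pass is returned with uncertainty exactly zero (also the
    n=1 case by the population-std convention). Deterministic per seed.
    """
    if n < 1:
        raise ValueError("number of passes must be >= 1")
    x = np.asarray(image, np.float32)[None, None]
    s = None if sppm is None else np.asarray(sppm, np.float32)[None, None]
    if model.cfg.dropout_rate == 0 or n == 1:
        with ad.no_grad():
            out = model(x, s, dropout_on=False)
        prob = out.data[0, 0]
        return TTDResult(prob=prob, uncertainty=np.zeros_like(prob), n=n)
    rng = np.random.default_rng(seed)
    passes = []
    chunk = 8  # batch stochastic passes through the network
    with ad.no_grad():
        remaining = n
        while remaining > 0:
            m = min(chunk, remaining)
            xb = np.repeat(x, m, axis=0)
            sb = None if s is None else np.repeat(s, m, axis=0)
            out = model(xb, sb, dropout_on=True, rng=rng)
            passes.extend(out.data[:, 0])
            remaining -= m
    prob, unc = mean_std_over_passes(np.stack(passes))
    return TTDResult(prob=np.clip(prob, 0.0, 1.0),
                     uncertainty=np.clip(unc, 0.0, 0.5), n=n)


def binarize(prob: np.ndarray, threshold: float = 0.5,
             affine=None) -> BinaryMask:
    """Threshold a probability grid into a mask (strictly greater-than)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    data = (prob > threshold).astype(np.uint8)
    if affine is None:
        return BinaryMask(data)
    return BinaryMask(data, affine)


def stitch_roi(mask: BinaryMask, box: ROIBox, full_shape,
               affine=None) -> BinaryMask:
    """Place an ROI mask back into the full volume grid (zeros outside)."""
    full_shape = tuple(full_shape)
    if mask.shape != (box.edge,) * 3:
        raise ValueError(f"mask shape {mask.shape} does not match ROI edge "
                         f"{box.edge}")
    if any(l < 0 or l + box.edge > s for l, s in zip(box.lo, full_shape)):
        raise ValueError(f"ROI box {box.lo}+{box.edge} exceeds grid "
                         f"{full_shape}")
    out = np.zeros(full_shape, dtype=np.uint8)
    out[box.slices] = mask.data
    if affine is None:
        return BinaryMask(out)
    return BinaryMask(out, affine)
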