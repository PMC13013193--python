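"""Loss, normalization, augmentation, the training loop and fold splitting.

Training follows the tiny-target segmentation recipe: the asymmetric
similarity loss (an F-beta generalization of the soft-Dice loss that
weights false negatives more heavily than false positives for beta > 1,
beta = 1.5 by default), Adam at learning rate 1e-3, mini-batches of two,
random 3D rotation augmentation, and model selection by the highest
validation Dice (threshold 0.5, dropout off).
"""

from __future__ import annotations

import copy
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import autodiff as ad
from .nn.unet import UNet
from .volume import BinaryMask, ImageVolume

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the small-structure recipe)."""

    beta: float = 1.5
    lr: float = 0.001
    batch_size: int = 2
    epochs: int = 60
    rotation_deg: tuple[float, float, float] = (10.0, 10.0, 10.0)
    #: SD of fresh Gaussian noise added to each (normalized) training image
    #: per step; exposes the network to new noise realizations every epoch
    noise_aug_sd: float = 0.0
    seed: int = 0
    val_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.beta <= 0 or self.lr <= 0 or self.batch_size < 1:
            raise ValueError("beta and lr must be positive, batch_size >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclass
class TrainHistory:
    """Per-epoch loss / validation-Dice curves and the selected epoch."""

    train_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = -1


def asymmetric_loss(pred, truth, beta: float = 1.5, eps: float = 1e-6):
    """Asymmetric similarity loss 1 - F_beta with soft counts.

    ``F_beta = (1+b^2) TP / ((1+b^2) TP + b^2 FN + FP)`` where TP/FP/FN are
    probability-weighted voxel counts; ``eps`` stabilizes the empty case.
    At ``beta=1`` this is exactly the soft-Dice loss. Accepts Tensors
    (differentiable) or arrays; reduces over all but the batch axis and
    returns the batch mean.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    pred_t = pred if isinstance(pred, ad.Tensor) else ad.Tensor(pred)
    truth_a = truth.data if isinstance(truth, (ad.Tensor, BinaryMask)) \
        else np.asarray(truth)
    truth_a = truth_a.astype(np.float32)
    if pred_t.shape != truth_a.shape:
        raise ValueError(f"prediction grid {pred_t.shape} differs from "
                         f"truth grid {truth_a.shape}")
    axes = tuple(range(1, pred_t.data.ndim)) or None
    b2 = beta * beta
    tp = ad.sum_(ad.mul(pred_t, truth_a), axis=axes)
    fn = ad.sum_(ad.mul(ad.sub(1.0, pred_t), truth_a), axis=axes)
    fp = ad.sum_(ad.mul(pred_t, 1.0 - truth_a), axis=axes)
    num = ad.add(ad.mul(tp, 1.0 + b2), eps)
    den = ad.add(ad.add(ad.mul(tp, 1.0 + b2), ad.add(ad.mul(fn, b2), fp)),
                 eps)
    loss = ad.mean(ad.sub(1.0, ad.div(num, den)))
    return loss if isinstance(pred, ad.Tensor) else float(loss.data)


def normalize_intensity(v: ImageVolume, clip: tuple[float, float] = (0.5, 99.5)
                        ) -> ImageVolume:
    """Robust min-max normalization to [0, 1].

    Intensities are clipped at the given percentiles before scaling, which
    makes the result invariant to affine intensity maps a*x+b (a > 0). A
    constant volume maps to 0.5 everywhere with a warning.
    """
    data = v.data.astype(np.float32)
    lo, hi = np.percentile(data, clip)
    if hi <= lo:
        warnings.warn("constant-intensity volume; normalizing to 0.5")
        return ImageVolume(np.full_like(data, 0.5), v.affine)
    out = (np.clip(data, lo, hi) - lo) / (hi - lo)
    return ImageVolume(out, v.affine)


def _rotate(data: np.ndarray, angles: np.ndarray, order: int) -> np.ndarray:
    center = (np.asarray(data.shape) - 1) / 2.0
    cx, cy, cz = np.deg2rad(angles)
    Rx = np.array([[1, 0, 0], [0, np.cos(cx), -np.sin(cx)],
                   [0, np.sin(cx), np.cos(cx)]])
    Ry = np.array([[np.cos(cy), 0, np.sin(cy)], [0, 1, 0],
                   [-np.sin(cy), 0, np.cos(cy)]])
    Rz = np.array([[np.cos(cz), -np.sin(cz), 0],
                   [np.sin(cz), np.cos(cz), 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    return ndimage.affine_transform(data, R, offset=center - R @ center,
                                    order=order, mode="constant", cval=0.0)


def augment_rotation(image: np.ndarray, mask: np.ndarray, sppm: np.ndarray,
                     rng: np.random.Generator,
                     ranges: tuple[float, float, float] = (10.0, 10.0, 10.0)):
    """One shared random 3D rotation of an (image, mask, SPPM-crop) triple.

    Linear interpolation for image and prior, nearest for the mask; zero
    ranges give the identity.
    """
    angles = np.array([rng.uniform(-r, r) if r > 0 else 0.0 for r in ranges])
    if not angles.any():
        return image, mask, sppm
    return (_rotate(image, angles, 1),
            (_rotate(mask.astype(np.float32), angles, 0) > 0.5).astype(
                mask.dtype),
            _rotate(sppm, angles, 1))


class Adam:
    """Adam optimizer over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _predict_case(model: UNet, image: np.ndarray, sppm) -> np.ndarray:
    with ad.no_grad():
        out = model(image[None, None],
                    None if sppm is None else sppm[None, None])
    return out.data[0, 0]


def _dice_arrays(pred: np.ndarray, truth: np.ndarray) -> float:
    # dimension-agnostic Dice (the metrics module serves 3D masks only)
    ps, ts = int(pred.sum()), int(truth.sum())
    if ps + ts == 0:
        return 1.0
    return 2.0 * float(np.logical_and(pred, truth).sum()) / (ps + ts)


def train(model: UNet, train_cases, val_cases,
          cfg: TrainConfig) -> tuple[UNet, TrainHistory]:
    """Train a network on ROI crops and return the best-validation weights.

    Each case is ``(image, sppm, label)`` of equal-shaped arrays (``sppm``
    may be None for non-priority networks). Per epoch: shuffle, rotate-
    augment, minimize the asymmetric loss with Adam; validation Dice is
    computed dropout-off at ``cfg.val_threshold`` and the weights of the
    best epoch are restored at the end. Fully deterministic given
    ``cfg.seed``.
    """
    if cfg.epochs > 0 and (not train_cases or not val_cases):
        raise ValueError("need at least one training and one validation case")
    history = TrainHistory()
    if cfg.epochs == 0:
        return model, history

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    uses_sppm = model.cfg.attention == "priority"
    best_state: dict | None = None
    best_dice = -1.0

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_cases))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = [train_cases[i] for i in order[start:start
                                                   + cfg.batch_size]]
            imgs, sppms, labels = [], [], []
            for image, sppm, label in batch:
                if model.cfg.dims == 3:
                    image, label, sppm = augment_rotation(
                        image, label,
                        sppm if sppm is not None else np.zeros_like(image),
                        rng, cfg.rotation_deg)
                if cfg.noise_aug_sd > 0:
                    image = image + rng.normal(
                        0, cfg.noise_aug_sd, image.shape).astype(np.float32)
                imgs.append(image)
                sppms.append(sppm)
                labels.append(label)
            x = np.stack(imgs)[:, None]
            y = np.stack(labels)[:, None].astype(np.float32)
            s = np.stack(sppms)[:, None] if uses_sppm else None
            out = model(x, s, dropout_on=model.cfg.dropout_rate > 0, rng=rng)
            loss = asymmetric_loss(out, y, beta=cfg.beta)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}; aborting "
                    "(check input normalization and learning rate)")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_scores = []
        for image, sppm, label in val_cases:
            prob = _predict_case(model, image, sppm if uses_sppm else None)
            val_scores.append(_dice_arrays(prob > cfg.val_threshold, label))
        history.train_loss.append(float(np.mean(losses)))
        history.val_dice.append(float(np.mean(val_scores)))
        if history.val_dice[-1] > best_dice:
            best_dice = history.val_dice[-1]
            history.best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
        log.info("epoch %d: loss %.4f, val dice %.4f", epoch,
                 history.train_loss[-1], history.val_dice[-1])

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, history


def make_folds(case_ids, k: int, seed: int) -> list[list]:
    """Random partition into k near-equal disjoint folds (sizes differ <= 1)."""
    case_ids = list(case_ids)
    if k < 1 or k > len(case_ids):
        raise ValueError(f"k={k} must be in [1, {len(case_ids)}]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    return [[case_ids[i] for i in chunk]
            for chunk in np.array_split(order, k)]
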