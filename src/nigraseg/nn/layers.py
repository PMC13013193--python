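"""Network building blocks: modules, convolutions, normalization, attention.

The attention gate follows the additive formulation: the skip feature x and
a gating signal g are each projected to a shared intermediate width, summed,
passed through ReLU, projected to one channel and squashed by a sigmoid into
an attention-coefficient map in [0, 1] that rescales x voxelwise. Two
flavours exist:

* classic gating — g is the decoder feature one scale coarser than x, so x
  is reduced to g's grid by a strided projection and the coefficient map is
  upsampled back (linear interpolation);
* priority gating — g is a learned convolution of the SN-prior probability
  map brought to x's own scale, so no resampling is needed and the prior's
  spatial information steers the attention directly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with recursive parameter/state traversal."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            params.extend(_collect_params(value))
        return params

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            _collect_state(value, f"{prefix}{name}", state)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray],
                        prefix: str = "") -> None:
        own = self.state_dict(prefix)
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for name, value in self.__dict__.items():
            _load_state(value, f"{prefix}{name}", state)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _collect_params(value):
    if isinstance(value, Tensor) and value.requires_grad:
        return [value]
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect_params(v))
        return out
    return []


def _collect_state(value, name, state):
    if isinstance(value, Tensor) and value.requires_grad:
        state[name] = value.data
    elif isinstance(value, Module):
        for k, v in value.state_dict(f"{name}.").items():
            state[k] = v
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_state(v, f"{name}.{i}", state)


def _load_state(value, name, state):
    if isinstance(value, Tensor) and value.requires_grad:
        arr = np.asarray(state[name], dtype=np.float32)
        if arr.shape != value.data.shape:
            raise ValueError(f"shape mismatch for {name}: "
                             f"{arr.shape} vs {value.data.shape}")
        value.data = arr.copy()
    elif isinstance(value, Module):
        value.load_state_dict(state, f"{name}.")
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _load_state(v, f"{name}.{i}", state)


class Conv(Module):
    """Convolution with He-normal init; 'same' padding by default."""

    def __init__(self, cin: int, cout: int, k: int, dims: int,
                 stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k ** dims
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (cout, cin) + (k,) * dims).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True)
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad

    def __call__(self, x):
        return ad.convnd(x, self.weight, self.bias, stride=self.stride,
                         pad=self.pad)


class InstanceNorm(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Preferred over batch statistics here because the networks train with
    mini-batches of two.
    """

    def __init__(self, channels: int, dims: int, eps: float = 1e-5):
        shape = (1, channels) + (1,) * dims
        self.gamma = Tensor(np.ones(shape, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, np.float32), requires_grad=True)
        self.eps = eps
        self._axes = tuple(range(2, 2 + dims))

    def __call__(self, x):
        m = ad.mean(x, axis=self._axes, keepdims=True)
        xc = ad.sub(x, m)
        v = ad.mean(ad.mul(xc, xc), axis=self._axes, keepdims=True)
        xn = ad.div(xc, ad.sqrt(ad.add(v, self.eps)))
        return ad.add(ad.mul(xn, self.gamma), self.beta)


class ConvBlock(Module):
    """Two 3x3(x3) convolutions, each followed by normalization and ReLU."""

    def __init__(self, cin: int, cout: int, dims: int, norm: str,
                 rng: np.random.Generator):
        self.conv1 = Conv(cin, cout, 3, dims, rng=rng)
        self.conv2 = Conv(cout, cout, 3, dims, rng=rng)
        self.norm1 = InstanceNorm(cout, dims) if norm == "instance" else None
        self.norm2 = InstanceNorm(cout, dims) if norm == "instance" else None

    def __call__(self, x):
        h = self.conv1(x)
        if self.norm1 is not None:
            h = self.norm1(h)
        h = ad.relu(h)
        h = self.conv2(h)
        if self.norm2 is not None:
            h = self.norm2(h)
        return ad.relu(h)


class AttentionGate(Module):
    """Additive attention gate producing coefficients in [0, 1].

    ``coarser=True`` expects g one scale below x (classic decoder gating);
    ``coarser=False`` expects g on x's own grid (prior gating).
    """

    def __init__(self, cx: int, cg: int, cmid: int, dims: int,
                 coarser: bool, rng: np.random.Generator):
        if coarser:
            self.theta = Conv(cx, cmid, 2, dims, stride=2, pad=0, rng=rng)
        else:
            self.theta = Conv(cx, cmid, 1, dims, rng=rng)
        self.phi = Conv(cg, cmid, 1, dims, rng=rng)
        self.psi = Conv(cmid, 1, 1, dims, rng=rng)
        self.coarser = coarser

    def __call__(self, x, g, attn_override=None):
        if attn_override is not None:
            a = ad._wrap(attn_override)
            return ad.mul(x, a), a
        q = ad.relu(ad.add(self.theta(x), self.phi(g)))
        a = ad.sigmoid(self.psi(q))
        if self.coarser:
            a = ad.upsample_linear2x(a)
        return ad.mul(x, a), a


def gated_attention(x, g, gate: AttentionGate, attn_override=None):
    """Apply an attention gate; returns (filtered feature, attention map)."""
    return gate(x, g, attn_override=attn_override)
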