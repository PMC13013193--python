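"""U-Net architectures: baseline, classic gated attention, priority gating.

The 3D network consumes a cubic neuromelanin-MRI region of interest (ROI)
and, in the priority variant, the matching crop of the registered SN-prior
probability map (SPPM). A small convolutional branch reduces the SPPM to
the scale and channel width of each encoder output; those features gate the
skip connections before concatenation into the decoder, concentrating
attention on the prior-plausible SN location even with little training
data. The 2D network is the same construction on axial slices, used for
midbrain segmentation of the T1-weighted channel.

Spatial dropout after every convolution block except the first encoder
level doubles as Monte-Carlo (test-time) dropout for uncertainty
estimation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .layers import AttentionGate, Conv, ConvBlock, Module


@dataclass
class NetConfig:
    """Architecture settings shared by the 2D and 3D networks."""

    depth: int = 4
    base_channels: int = 16
    dropout_rate: float = 0.2
    in_shape: int = 64
    attention: str = "priority"  # none | gated | priority
    norm: str = "instance"  # instance | none
    dims: int = 3
    init_seed: int = 0
    #: initial bias of the output convolution; a negative value starts the
    #: network predicting background, which speeds up convergence when the
    #: foreground occupies a tiny fraction of the volume
    final_bias: float = -2.0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.in_shape % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"in_shape {self.in_shape} not divisible by "
                f"2^(depth-1) = {2 ** (self.depth - 1)}")
        if self.attention not in ("none", "gated", "priority"):
            raise ValueError(f"unknown attention mode {self.attention!r}")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def channels(self) -> list[int]:
        return [self.base_channels * 2 ** i for i in range(self.depth)]


class UNet(Module):
    """Encoder-decoder with optional attention-gated skip connections."""

    def __init__(self, cfg: NetConfig):
        rng = np.random.default_rng(cfg.init_seed)
        self.cfg = cfg
        d, ch, dims = cfg.depth, cfg.channels, cfg.dims

        # strided convolutions do the downsampling, so the encoder block at
        # level i>0 sees ch[i] channels from down[i-1]
        self.enc = [ConvBlock(1, ch[0], dims, cfg.norm, rng)] + \
            [ConvBlock(ch[i], ch[i], dims, cfg.norm, rng) for i in range(1, d)]
        self.down = [Conv(ch[i], ch[i + 1], 3, dims, stride=2, rng=rng)
                     for i in range(d - 1)]

        self.upconv = [Conv(ch[i + 1], ch[i], 3, dims, rng=rng)
                       for i in range(d - 1)]
        self.dec = [ConvBlock(2 * ch[i], ch[i], dims, cfg.norm, rng)
                    for i in range(d - 1)]
        self.final = Conv(ch[0], 1, 1, dims, rng=rng)
        self.final.bias.data[:] = cfg.final_bias

        self.gates: list[AttentionGate] | None = None
        self.sppm_branch: list[Conv] | None = None
        if cfg.attention == "gated":
            self.gates = [AttentionGate(ch[i], ch[i + 1], ch[i], dims,
                                        coarser=True, rng=rng)
                          for i in range(d - 1)]
        elif cfg.attention == "priority":
            self.gates = [AttentionGate(ch[i], ch[i], ch[i], dims,
                                        coarser=False, rng=rng)
                          for i in range(d - 1)]
            self.sppm_branch = [Conv(1, ch[i], 3, dims,
                                     stride=2 ** i, pad=1, rng=rng)
                                for i in range(d - 1)]

        self.last_attention: list[np.ndarray] = []

    def forward(self, x, sppm=None, dropout_on: bool = False,
                rng: np.random.Generator | None = None,
                attn_override=None):
        """Forward pass; returns voxelwise probabilities on the input grid.

        ``x``: (N, 1, *spatial) array or Tensor; ``sppm`` required for
        priority attention, on the same grid as ``x``. ``attn_override``
        replaces every attention map with a constant (diagnostics).
        """
        cfg = self.cfg
        x = ad._wrap(x)
        if cfg.attention == "priority":
            if sppm is None:
                raise ValueError("priority attention requires an SPPM crop")
            sppm = ad._wrap(sppm)
            if sppm.shape[2:] != x.shape[2:]:
                raise ValueError("SPPM crop grid differs from input grid")
        if dropout_on and rng is None:
            rng = np.random.default_rng(0)

        def drop(t):
            return ad.spatial_dropout(t, cfg.dropout_rate, rng, on=dropout_on)

        sppm_feats = None
        if self.sppm_branch is not None:
            sppm_feats = [branch(sppm) for branch in self.sppm_branch]

        skips = []
        h = x
        for i in range(cfg.depth):
            h = self.enc[i](h)
            if i > 0:
                h = drop(h)
            if i < cfg.depth - 1:
                skips.append(h)
                h = self.down[i](h)

        self.last_attention = []
        for i in reversed(range(cfg.depth - 1)):
            gating = h  # decoder state one scale coarser than skips[i]
            up = self.upconv[i](ad.upsample_nearest2x(h))
            skip = skips[i]
            if self.gates is not None:
                g = sppm_feats[i] if sppm_feats is not None else gating
                skip, attn = self.gates[i](skip, g,
                                           attn_override=attn_override)
                self.last_attention.insert(0, attn.data)
            h = drop(self.dec[i](ad.concat([up, skip], axis=1)))
        return ad.sigmoid(self.final(h))

    __call__ = forward


def build_unet3d(cfg: NetConfig) -> UNet:
    """3D SN-segmentation network per the configured attention mode."""
    if cfg.dims != 3:
        raise ValueError("build_unet3d requires cfg.dims == 3")
    return UNet(cfg)


def build_unet2d(cfg: NetConfig) -> UNet:
    """2D midbrain-segmentation network (axial T1 slices)."""
    if cfg.dims != 2:
        raise ValueError("build_unet2d requires cfg.dims == 2")
    return UNet(cfg)


def save_model(model: UNet, path) -> None:
    """Persist weights (.npz) with a JSON sidecar of the configuration."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    path.with_suffix(".json").write_text(json.dumps(asdict(model.cfg)))


def load_model(path) -> UNet:
    path = Path(path)
    cfg = NetConfig(**json.loads(path.with_suffix(".json").read_text()))
    model = UNet(cfg)
    with np.load(path if path.suffix == ".npz"
                 else path.with_suffix(".npz")) as st:
        model.load_state_dict({k: st[k] for k in st.files})
    return model
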