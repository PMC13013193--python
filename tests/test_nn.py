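"""Autodiff engine and network architectures."""

import numpy as np
import pytest

from nigraseg.nn import autodiff as ad
from nigraseg.nn.layers import AttentionGate
from nigraseg.nn.unet import (NetConfig, UNet, build_unet2d, build_unet3d,
                              load_model, save_model)


def _numeric_grad(f, arr, eps=1e-3):
    g = np.zeros_like(arr, dtype=np.float64)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g


class TestAutodiffGradients:
    @pytest.mark.parametrize("stride,pad,shape,kshape", [
        (1, None, (1, 2, 5, 5, 5), (3, 2, 3, 3, 3)),
        (2, None, (1, 2, 6, 6, 6), (2, 2, 3, 3, 3)),
        (2, 0, (1, 2, 6, 6), (3, 2, 2, 2)),
        (4, 1, (1, 1, 8, 8, 8), (2, 1, 3, 3, 3)),
    ])
    def test_conv_matches_finite_differences(self, stride, pad, shape,
                                             kshape):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, shape).astype(np.float32)
        w = rng.normal(0, 0.5, kshape).astype(np.float32)
        b = rng.normal(0, 0.5, kshape[0]).astype(np.float32)

        def run():
            return ad.convnd(ad.Tensor(x), ad.Tensor(w), ad.Tensor(b),
                             stride=stride, pad=pad)

        tx, tw, tb = ad.Tensor(x), ad.Tensor(w), ad.Tensor(b)
        out = ad.convnd(tx, tw, tb, stride=stride, pad=pad)
        ad.sum_(ad.mul(out, out)).backward()
        for t, arr in ((tx, x), (tw, w), (tb, b)):
            ng = _numeric_grad(
                lambda: float((run().data.astype(np.float64) ** 2).sum()),
                arr)
            rel = np.abs(ng - t.grad).max() / (np.abs(ng).max() + 1e-8)
            assert rel < 2e-2

    @pytest.mark.parametrize("op", [ad.upsample_nearest2x,
                                    ad.upsample_linear2x])
    def test_upsampling_adjoint(self, op):
        # for a linear operator L, <L x, y> must equal <x, L^T y>
        rng = np.random.default_rng(1)
        x = ad.Tensor(rng.normal(0, 1, (2, 3, 4, 4)).astype(np.float32))
        y = rng.normal(0, 1, (2, 3, 8, 8)).astype(np.float32)
        out = op(x)
        out.backward(y)
        lhs = float((out.data.astype(np.float64) * y).sum())
        rhs = float((x.data.astype(np.float64) * x.grad).sum())
        assert lhs == pytest.approx(rhs, rel=1e-4)

    def test_instance_norm_chain_gradient(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (2, 3, 4, 4)).astype(np.float32)

        def build(t):
            m = ad.mean(t, axis=(2, 3), keepdims=True)
            xc = ad.sub(t, m)
            v = ad.mean(ad.mul(xc, xc), axis=(2, 3), keepdims=True)
            return ad.mul(ad.sigmoid(ad.div(xc, ad.sqrt(ad.add(v, 1e-5)))),
                          t)

        t = ad.Tensor(x)
        ad.sum_(build(t)).backward()
        ng = _numeric_grad(
            lambda: float(build(ad.Tensor(x)).data.astype(np.float64).sum()),
            x)
        assert np.abs(ng - t.grad).max() / np.abs(ng).max() < 2e-2

    def test_no_grad_builds_no_tape(self):
        x = ad.Tensor(np.ones((2, 2), np.float32))
        with ad.no_grad():
            y = ad.mul(x, 2.0)
        assert y._backward is None and y._parents == ()


class TestAttentionGate:
    def _gate_and_inputs(self, coarser):
        rng = np.random.default_rng(3)
        gate = AttentionGate(cx=4, cg=6 if coarser else 4, cmid=4, dims=3,
                             coarser=coarser, rng=rng)
        x = ad.Tensor(rng.normal(0, 1, (1, 4, 8, 8, 8)).astype(np.float32))
        gshape = (1, 6, 4, 4, 4) if coarser else (1, 4, 8, 8, 8)
        g = ad.Tensor(rng.normal(0, 1, gshape).astype(np.float32))
        return gate, x, g

    @pytest.mark.parametrize("coarser", [False, True])
    def test_coefficients_in_unit_interval_and_attenuating(self, coarser):
        gate, x, g = self._gate_and_inputs(coarser)
        filtered, attn = gate(x, g)
        assert attn.data.min() > 0.0 and attn.data.max() < 1.0
        assert np.all(np.abs(filtered.data) <= np.abs(x.data) + 1e-6)
        assert filtered.shape == x.shape

    def test_override_identity_and_zero(self):
        gate, x, g = self._gate_and_inputs(False)
        filtered, _ = gate(x, g, attn_override=np.float32(1.0))
        np.testing.assert_array_equal(filtered.data, x.data)
        filtered, _ = gate(x, g, attn_override=np.float32(0.0))
        assert np.abs(filtered.data).max() == 0.0


class TestNetConfig:
    def test_shape_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            NetConfig(depth=4, in_shape=60)

    def test_depth_minimum(self):
        with pytest.raises(ValueError, match="depth"):
            NetConfig(depth=1)


@pytest.fixture(scope="module")
def small3d():
    return build_unet3d(NetConfig(depth=3, base_channels=4, in_shape=16,
                                  attention="priority", init_seed=0))


class TestUNet:
    def test_output_shape_and_range_3d(self, small3d):
        rng = np.random.default_rng(4)
        x = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        s = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        with ad.no_grad():
            out = small3d(x, s)
        assert out.shape == x.shape
        assert 0.0 <= out.data.min() and out.data.max() <= 1.0
        for attn in small3d.last_attention:
            assert attn.min() >= 0.0 and attn.max() <= 1.0

    def test_ablation_same_shape_no_attention_params(self):
        plain = build_unet3d(NetConfig(depth=3, base_channels=4, in_shape=16,
                                       attention="none", init_seed=0))
        x = np.random.default_rng(5).random((1, 1, 16, 16, 16),
                                            dtype=np.float32)
        with ad.no_grad():
            out = plain(x)
        assert out.shape == x.shape
        assert plain.gates is None and plain.sppm_branch is None

    def test_priority_has_more_parameters(self, small3d):
        plain = build_unet3d(NetConfig(depth=3, base_channels=4, in_shape=16,
                                       attention="none", init_seed=0))
        assert small3d.num_parameters() > plain.num_parameters()

    def test_priority_requires_sppm(self, small3d):
        x = np.zeros((1, 1, 16, 16, 16), np.float32)
        with pytest.raises(ValueError, match="SPPM"):
            small3d(x)
        with pytest.raises(ValueError, match="grid"):
            small3d(x, np.zeros((1, 1, 8, 8, 8), np.float32))

    def test_dropout_off_deterministic(self, small3d):
        rng = np.random.default_rng(6)
        x = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        s = rng.random((1, 1, 16, 16, 16), dtype=np.float32)
        with ad.no_grad():
            a = small3d(x, s).data
            b = small3d(x, s).data
        np.testing.assert_array_equal(a, b)

    def test_uniform_sppm_gives_flat_attention_interior(self, small3d):
        x = np.random.default_rng(7).random((1, 1, 16, 16, 16),
                                            dtype=np.float32)
        s = np.full((1, 1, 16, 16, 16), 0.5, np.float32)
        # constant input to the SPPM branch -> constant gating away from
        # padding borders; check the finest-scale attention interior
        with ad.no_grad():
            small3d(x * 0, s)
        attn = small3d.last_attention[0][0, 0]
        interior = attn[4:-4, 4:-4, 4:-4]
        assert np.ptp(interior) < 1e-4

    def test_2d_shapes_and_finiteness(self):
        net = build_unet2d(NetConfig(depth=3, base_channels=4, in_shape=32,
                                     attention="none", dims=2, init_seed=1))
        with ad.no_grad():
            out = net(np.zeros((2, 1, 32, 32), np.float32))
        assert out.shape == (2, 1, 32, 32)
        assert np.all(np.isfinite(out.data))
        x = np.random.default_rng(8).random((1, 1, 32, 32), dtype=np.float32)
        with ad.no_grad():
            a, b = net(x).data, net(x).data
        np.testing.assert_array_equal(a, b)

    def test_translation_equivariance_interior(self):
        # bias-free interiors of CNN outputs must track an 8-voxel shift
        cfg = NetConfig(depth=2, base_channels=4, in_shape=48,
                        attention="none", norm="none", init_seed=2,
                        final_bias=0.0)
        net = build_unet3d(cfg)
        rng = np.random.default_rng(9)
        x = rng.random((1, 1, 48, 48, 48), dtype=np.float32)
        xs = np.roll(x, 8, axis=2)
        with ad.no_grad():
            a = net(x).data[0, 0]
            b = net(xs).data[0, 0]
        # exclude a receptive-field margin from every border
        inner = (slice(20, 36), slice(14, 34), slice(14, 34))
        np.testing.assert_allclose(np.roll(a, 8, axis=0)[inner], b[inner],
                                   atol=1e-4)

    def test_save_load_roundtrip(self, small3d, tmp_path):
        save_model(small3d, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        x = np.random.default_rng(10).random((1, 1, 16, 16, 16),
                                             dtype=np.float32)
        s = np.random.default_rng(11).random((1, 1, 16, 16, 16),
                                             dtype=np.float32)
        with ad.no_grad():
            np.testing.assert_array_equal(small3d(x, s).data,
                                          back(x, s).data)
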