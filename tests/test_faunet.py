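"""FAUnet: shape contracts, determinism, HFSM algebra, gradient flow."""

import numpy as np
import pytest

from fadm import nn
from fadm.faunet import HFSM, DenoiserConfig, FAUnet, WaveletDownsample
from fadm.nn import Tensor


def make_inputs(rng, c=1, size=32, n=2):
    """Packed X_t, packed conditional, raw conditional, per-sample t."""
    from fadm.wavelet import dwt2, pack_subbands

    xt = rng.uniform(-1, 1, size=(n, c, size, size))
    cond = rng.uniform(-1, 1, size=(n, c, size, size))
    return (pack_subbands(dwt2(xt)), pack_subbands(dwt2(cond)), cond,
            np.array([3] * n))


class TestConfig:
    def test_round_trip_through_dict(self):
        cfg = DenoiserConfig(levels=3, channel_multipliers=(1, 2, 4),
                             attn_levels=(3,), hfsm_levels=(1, 2))
        assert DenoiserConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize("kwargs", [
        dict(levels=0, channel_multipliers=()),
        dict(channel_multipliers=(1,)),              # wrong length for levels=2
        dict(hfsm_levels=(3,)),                      # outside 1..levels
        dict(time_embed_dim=33),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DenoiserConfig(**kwargs)


class TestForward:
    @pytest.mark.parametrize("levels,mults,c", [(2, (1, 2), 1), (3, (1, 1, 2), 1),
                                                (2, (1, 2), 3)])
    def test_output_shape_matches_packed_input(self, rng, levels, mults, c):
        cfg = DenoiserConfig(levels=levels, channel_multipliers=mults,
                             base_channels=8, hfsm_levels=tuple(range(1, levels + 1)),
                             in_channels=8 * c, out_channels=4 * c, cond_channels=c)
        net = FAUnet(cfg, seed=0)
        xt_p, y_p, cond, t = make_inputs(rng, c=c)
        out = net(xt_p, y_p, cond, t)
        assert out.shape == xt_p.shape

    def test_deterministic_given_inputs(self, rng):
        net = FAUnet(DenoiserConfig(), seed=0)
        args = make_inputs(rng)
        np.testing.assert_array_equal(net(*args).data, net(*args).data)

    def test_construction_is_pure_function_of_seed(self):
        a = FAUnet(DenoiserConfig(), seed=5).state_dict()
        b = FAUnet(DenoiserConfig(), seed=5).state_dict()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_time_embedding_is_live(self, rng):
        net = FAUnet(DenoiserConfig(), seed=0)
        xt_p, y_p, cond, _ = make_inputs(rng)
        # run one optimizer step first: residual/output projections start at
        # zero, which mutes the time pathway at exact initialization
        opt = nn.AdamW(net.parameters(), lr=1e-2)
        target = Tensor(rng.normal(size=xt_p.shape))
        for _ in range(2):
            diff = net(xt_p, y_p, cond, 3) - target
            net.zero_grad()
            (diff * diff).mean().backward()
            opt.step()
        o1 = net(xt_p, y_p, cond, 2).data
        o2 = net(xt_p, y_p, cond, 17).data
        assert np.abs(o1 - o2).max() > 1e-10

    def test_mismatched_packed_inputs_rejected(self, rng):
        net = FAUnet(DenoiserConfig(), seed=0)
        xt_p, y_p, cond, t = make_inputs(rng)
        with pytest.raises(ValueError, match="shapes differ"):
            net(xt_p, y_p[:, :, :8], cond, t)

    def test_all_parameters_receive_gradient(self, rng):
        """No dead branches: after a couple of steps every parameter sees a
        nonzero gradient (zero-initialized projections need one step to
        open their upstream paths)."""
        net = FAUnet(DenoiserConfig(attn_levels=(2,)), seed=0)
        opt = nn.AdamW(net.parameters(), lr=1e-2)
        xt_p, y_p, cond, t = make_inputs(rng)
        target = Tensor(rng.normal(size=xt_p.shape))
        for _ in range(2):
            diff = net(xt_p, y_p, cond, t) - target
            loss = (diff * diff).mean()
            opt.zero_grad()
            net.zero_grad()
            loss.backward()
            opt.step()
        diff = net(xt_p, y_p, cond, t) - target
        net.zero_grad()
        (diff * diff).mean().backward()
        dead = [k for k, p in net.parameters().items()
                if p.grad is None or np.all(p.grad == 0)]
        assert not dead, f"parameters with zero gradient: {dead}"


class TestWaveletDownsample:
    def test_halves_spatial_dims_and_projects_channels(self, rng):
        layer = WaveletDownsample(4, 16, rng)
        out = layer(Tensor(rng.normal(size=(2, 4, 8, 8))))
        assert out.shape == (2, 16, 4, 4)

    def test_constant_input_has_zero_detail_channels(self):
        x = Tensor(np.full((1, 2, 8, 8), 0.5))
        packed = nn.haar_packed(x)
        assert np.allclose(packed.data[:, 2:], 0.0)  # lh, hl, hh blocks
        assert np.allclose(packed.data[:, :2], 1.0)

    def test_transform_stage_preserves_energy(self, rng):
        x = Tensor(rng.normal(size=(1, 3, 8, 8)))
        packed = nn.haar_packed(x)
        assert np.sum(packed.data**2) == pytest.approx(np.sum(x.data**2), rel=1e-10)

    def test_odd_dims_rejected(self, rng):
        layer = WaveletDownsample(1, 4, rng)
        with pytest.raises(ValueError, match="even"):
            layer(Tensor(np.zeros((1, 1, 7, 8))))


class TestHFSM:
    def test_output_shape_equals_feature_shape(self, rng):
        mod = HFSM(1, 8, rng)
        m = Tensor(rng.normal(size=(2, 8, 4, 4)))
        det = Tensor(rng.normal(size=(2, 1, 4, 4)))
        assert mod(m, det).shape == m.shape

    def test_spatial_mismatch_names_both_shapes(self, rng):
        mod = HFSM(1, 8, rng)
        with pytest.raises(ValueError, match=r"\(4, 4\).*\(2, 2\)"):
            mod(Tensor(np.zeros((1, 8, 4, 4))), Tensor(np.zeros((1, 1, 2, 2))))

    def test_constant_keys_average_values(self, rng):
        """Uniform softmax: with K constant over positions every output
        position is the mean of the value rows."""
        mod = HFSM(1, 4, rng)
        # force K projection to a constant map: zero weight, fixed bias
        mod.k.weight.data[:] = 0.0
        mod.k.bias.data[:] = 1.0
        m = Tensor(rng.normal(size=(1, 4, 3, 3)))
        det = Tensor(rng.normal(size=(1, 1, 3, 3)))
        out = mod(m, det).data.reshape(4, 9)
        v = nn.conv2d(m, mod.v.weight, mod.v.bias).data.reshape(4, 9)
        expected = v.mean(axis=1, keepdims=True) * np.ones((1, 9))
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_matches_brute_force_attention(self, rng):
        """2×2 toy feature map with identity projections equals the
        hand-computable softmax(QKᵀ/√d_k)·V."""
        d = 3
        mod = HFSM(d, d, rng)
        for conv in (mod.q, mod.k, mod.v):
            conv.weight.data = np.eye(d).reshape(d, d, 1, 1)
            conv.bias.data[:] = 0.0
        m = rng.normal(size=(1, d, 2, 2))
        det = rng.normal(size=(1, d, 2, 2))
        out = mod(Tensor(m), Tensor(det)).data.reshape(d, 4).T

        q = det.reshape(d, 4).T
        k = m.reshape(d, 4).T
        v = m.reshape(d, 4).T
        logits = q @ k.T / np.sqrt(d)
        w = np.exp(logits - logits.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(out, w @ v, atol=1e-10)


class TestStrippedVariant:
    def test_strided_downsampling_still_preserves_shapes(self, rng):
        cfg = DenoiserConfig(hfsm_levels=(), use_wavelet_downsample=False)
        net = FAUnet(cfg, seed=0)
        xt_p, y_p, cond, t = make_inputs(rng)
        assert net(xt_p, y_p, cond, t).shape == xt_p.shape

    def test_stripped_has_fewer_parameters(self):
        full = FAUnet(DenoiserConfig(), seed=0)
        stripped = FAUnet(DenoiserConfig(hfsm_levels=(),
                                         use_wavelet_downsample=False), seed=0)
        n_full = sum(p.data.size for p in full.parameters().values())
        n_stripped = sum(p.data.size for p in stripped.parameters().values())
        assert n_stripped < n_full
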