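"""Training loop and sampler: loss contract, checkpoints, determinism."""

import numpy as np
import pytest

from fadm import bridge, wavelet
from fadm import train_sample as ts
from fadm.conditioning import IdentityProvider
from fadm.data import make_dataset, pairs_to_arrays
from fadm.faunet import DenoiserConfig, FAUnet
from fadm.nn import AdamW, Tensor


@pytest.fixture(scope="module")
def tiny_setup():
    splits = make_dataset(10, 2, seed=0)
    tr = pairs_to_arrays(splits.train)
    va = pairs_to_arrays(splits.val)
    cfg = DenoiserConfig(base_channels=8)
    return splits, tr, va, cfg


class TestTrainingStep:
    def test_loss_nonnegative_and_finite(self, tiny_setup, rng):
        _, (src, tgt), _, cfg = tiny_setup
        net = FAUnet(cfg, seed=0)
        sched = bridge.make_schedule(10)
        opt = AdamW(net.parameters(), lr=1e-3)
        loss = ts.training_step(src[:2], tgt[:2], IdentityProvider(), net,
                                sched, opt, rng)
        assert np.isfinite(loss) and loss >= 0.0

    def test_oracle_prediction_gives_zero_loss(self, tiny_setup):
        """Feeding back the exact packed ε yields exactly zero loss."""
        _, (src, tgt), _, _ = tiny_setup
        sched = bridge.make_schedule(10)

        class Oracle:
            def __call__(self, xt_packed, y_packed, cond, t):
                xt = wavelet.idwt2(wavelet.unpack_subbands(xt_packed))
                x0 = tgt[:2]
                sig = np.sqrt(sched.sigma2_fwd[np.asarray(t)])[:, None, None, None]
                return Tensor(wavelet.pack_subbands(wavelet.dwt2((xt - x0) / sig)))

        loss = ts.training_step(src[:2], tgt[:2], IdentityProvider(), Oracle(),
                                sched, None, np.random.default_rng(0))
        assert loss < 1e-20  # zero up to the DWT round-trip float error

    def test_wavelet_domain_mse_equals_pixel_domain(self, rng):
        """Orthonormality makes the packed-domain objective identical to the
        pixel-domain one."""
        a = rng.normal(size=(2, 1, 16, 16))
        b = rng.normal(size=(2, 1, 16, 16))
        pa = wavelet.pack_subbands(wavelet.dwt2(a))
        pb = wavelet.pack_subbands(wavelet.dwt2(b))
        assert np.mean((pa - pb) ** 2) == pytest.approx(np.mean((a - b) ** 2))


class TestSampler:
    def test_oracle_sampler_reaches_target_through_plumbing(self, rng):
        """DWT → pack → predict → unpack → IWT → reverse step, iterated, is
        exact when the predictor is the true ε."""
        sched = bridge.make_schedule(20)
        from fadm.data import make_phantom_pair

        pair = make_phantom_pair(5, 32)
        x0 = pair.target[None]

        def oracle(xt_packed, y_packed, cond, t):
            xt = wavelet.idwt2(wavelet.unpack_subbands(xt_packed))
            return wavelet.pack_subbands(
                wavelet.dwt2(bridge.epsilon_target(x0, xt, t, sched)))

        out = ts.sample(pair.source, IdentityProvider(), oracle, sched, rng)
        assert out.shape == pair.source.shape
        assert np.sqrt(np.mean((out - pair.target) ** 2)) < 1e-3

    def test_fixed_seed_reproducibility(self, tiny_setup):
        _, (src, tgt), _, cfg = tiny_setup
        net = FAUnet(cfg, seed=0)
        sched = bridge.make_schedule(5)
        a = ts.sample(src[0], IdentityProvider(), net, sched,
                      np.random.default_rng(9))
        b = ts.sample(src[0], IdentityProvider(), net, sched,
                      np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_cost_linear_in_inference_steps(self, tiny_setup):
        _, (src, _), _, cfg = tiny_setup
        sched = bridge.make_schedule(20)
        calls = []

        def counting_net(xt_packed, y_packed, cond, t):
            calls.append(t)
            return np.zeros_like(xt_packed)

        ts.sample(src[0], IdentityProvider(), counting_net, sched,
                  np.random.default_rng(0), n_infer_steps=5)
        assert len(calls) == 5
        calls.clear()
        ts.sample(src[0], IdentityProvider(), counting_net, sched,
                  np.random.default_rng(0))
        assert len(calls) == 20


class TestCheckpointSelect:
    @pytest.mark.parametrize("losses,expected", [([3.0, 2.0, 4.0], 1),
                                                 ([2.0, 2.0], 1),
                                                 ([5.0], 0)])
    def test_argmin_with_later_tie_break(self, losses, expected):
        assert ts.checkpoint_select(losses) == expected

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ts.checkpoint_select([])


class TestTrainOrchestration:
    def test_short_run_contract(self, tiny_setup, tmp_path):
        _, tr, va, cfg = tiny_setup
        tcfg = ts.desk_train_config(max_iterations=20, validation_interval=10,
                                    seed=1, checkpoint_dir=str(tmp_path))
        res = ts.train(tcfg, cfg, tr, va, IdentityProvider(),
                       log_path=tmp_path / "log.tsv")
        assert len(res.train_losses) == 20
        assert len(res.val_history) == 2
        assert (tmp_path / "log.tsv").read_text().startswith("iteration")
        assert (tmp_path / "best.npz").exists()

    def test_checkpoint_round_trip(self, tiny_setup, tmp_path):
        _, (src, tgt), va, cfg = tiny_setup
        tcfg = ts.desk_train_config(max_iterations=5, validation_interval=5, seed=2)
        res = ts.train(tcfg, cfg, (src, tgt), va, IdentityProvider())
        path = tmp_path / "ck.npz"
        ts.save_checkpoint(path, res.net, tcfg, res.sched, res.best_iteration)
        net2, tcfg2, sched2, it = ts.load_checkpoint(path)
        assert tcfg2 == tcfg and it == res.best_iteration
        np.testing.assert_array_equal(sched2.beta, res.sched.beta)
        a = ts.sample(src[0], IdentityProvider(), res.net, res.sched,
                      np.random.default_rng(3))
        b = ts.sample(src[0], IdentityProvider(), net2, sched2,
                      np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)

    def test_nonfinite_loss_aborts_with_diagnostics(self, tiny_setup):
        _, (src, tgt), _, cfg = tiny_setup

        class NanNet:
            def __call__(self, xt_packed, y_packed, cond, t):
                return Tensor(np.full_like(xt_packed, np.nan))

        with pytest.raises(FloatingPointError, match="t="):
            ts.training_step(src[:2], tgt[:2], IdentityProvider(), NanNet(),
                             bridge.make_schedule(10), None,
                             np.random.default_rng(0))
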