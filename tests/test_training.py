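"""Losses against scalar hand-computation, schedule, determinism, resume."""

import numpy as np
import pytest

from fodgan import autodiff as ad
from fodgan import training as tr
from fodgan.networks import TINY_SCALE
from fodgan.sh import SHBasis, SHImage


def _scalar_bundle():
    """One-voxel 'images', batch 1, matching the hand-arithmetic oracles."""
    t = lambda v: ad.tensor(np.array([[v]]))
    return tr.BatchBundle(x_train=t(0.5), z_r=t(0.4), x_syn=t(-0.2),
                          z_e=t(0.1), x_dec=t(0.3))


_IDENT = lambda x: x


class TestLossOracles:
    def test_loss_ge_hand_arithmetic(self):
        # -0.3 - (-0.2) - 0.1 + 10*0.2 = 1.8
        assert tr.loss_ge(_scalar_bundle(), _IDENT, _IDENT, 10.0).item() \
            == pytest.approx(1.8, abs=1e-12)

    def test_loss_ge_zero_when_reconstruction_perfect_and_critics_silent(self):
        b = _scalar_bundle()
        b.x_dec = b.x_train
        zero = lambda x: ad.tensor(np.zeros((x.shape[0], 1)))
        assert tr.loss_ge(b, zero, zero, 50000.0).item() == 0.0

    def test_lambda_zero_ignores_reconstruction_error(self):
        b1, b2 = _scalar_bundle(), _scalar_bundle()
        b2.x_dec = ad.tensor(np.array([[0.3]]))  # same critic input
        b2.x_train = ad.tensor(np.array([[-7.0]]))  # huge recon error
        assert tr.loss_ge(b1, _IDENT, _IDENT, 0.0).item() \
            == pytest.approx(tr.loss_ge(b2, _IDENT, _IDENT, 0.0).item())

    def test_loss_d_hand_arithmetic(self):
        # 0.3 + (-0.2) - 2*0.5 = -0.9
        assert tr.loss_d(_scalar_bundle(), _IDENT, 0.0).item() \
            == pytest.approx(-0.9, abs=1e-12)

    def test_loss_d_constant_critic_cancels(self):
        const = lambda x: ad.tensor(np.full((x.shape[0], 1), 3.3))
        assert tr.loss_d(_scalar_bundle(), const, 0.0).item() == 0.0

    def test_loss_cd_hand_arithmetic(self):
        # 0.1 - 0.4 = -0.3
        assert tr.loss_cd(_scalar_bundle(), _IDENT, 0.0).item() \
            == pytest.approx(-0.3, abs=1e-12)

    def test_l1_term_is_mean_of_per_sample_sums(self):
        x = ad.tensor(np.arange(12.0).reshape(2, 6))
        y = ad.tensor(np.zeros((2, 6)))
        zero = lambda t: ad.tensor(np.zeros((t.shape[0], 1)))
        b = tr.BatchBundle(x_train=x, z_r=y, x_syn=y, z_e=y, x_dec=y)
        per_sample = np.abs(np.arange(12.0).reshape(2, 6)).sum(axis=1)
        assert tr.loss_ge(b, zero, zero, 1.0).item() \
            == pytest.approx(per_sample.mean())


class TestGradientPenalty:
    def _draws(self, rng, n=4):
        return tr.InterpolantDraw.sample(rng, n)

    def test_unit_norm_linear_critic_zero_penalty(self, rng):
        w = rng.standard_normal(7)
        w /= np.linalg.norm(w)
        D = lambda t: ad.matmul(t, ad.tensor(w[:, None]))
        pen = tr.gradient_penalty_d(D, rng.standard_normal((4, 7)),
                                    rng.standard_normal((4, 7)),
                                    rng.standard_normal((4, 7)), self._draws(rng))
        assert abs(pen.item()) < 1e-6

    def test_slope_two_critic_gives_two(self, rng):
        w = np.array([2.0, 0, 0, 0])
        D = lambda t: ad.matmul(t, ad.tensor(w[:, None]))
        pen = tr.gradient_penalty_d(D, rng.standard_normal((3, 4)),
                                    rng.standard_normal((3, 4)),
                                    rng.standard_normal((3, 4)), self._draws(rng, 3))
        assert pen.item() == pytest.approx(2.0, abs=1e-6)

    def test_constant_critic_gives_two(self, rng):
        D = lambda t: ad.tensor(np.zeros((t.shape[0], 1)))
        pen = tr.gradient_penalty_d(D, rng.standard_normal((3, 4)),
                                    rng.standard_normal((3, 4)),
                                    rng.standard_normal((3, 4)), self._draws(rng, 3))
        assert pen.item() == pytest.approx(2.0, abs=1e-4)

    def test_invariant_under_batch_permutation(self, rng):
        w = rng.standard_normal((6, 1))
        D = lambda t: ad.tanh(ad.matmul(t, ad.tensor(w)))
        xt, xs, xd = (rng.standard_normal((5, 6)) for _ in range(3))
        draws = self._draws(rng, 5)
        pen = tr.gradient_penalty_d(D, xt, xs, xd, draws)
        perm = rng.permutation(5)
        pdraws = tr.InterpolantDraw(draws.alpha[perm], draws.beta[perm],
                                    draws.gamma[perm])
        pen_p = tr.gradient_penalty_d(D, xt[perm], xs[perm], xd[perm], pdraws)
        assert pen_p.item() == pytest.approx(pen.item(), rel=1e-6)

    def test_cd_penalty_single_interpolant(self, rng):
        CD = lambda t: ad.tensor(np.zeros((t.shape[0], 1)))
        pen = tr.gradient_penalty_cd(CD, rng.standard_normal((3, 5)),
                                     rng.standard_normal((3, 5)), self._draws(rng, 3))
        assert pen.item() == pytest.approx(1.0, abs=1e-4)


class TestNormalization:
    def _image(self, rng):
        return SHImage(rng.standard_normal((6, 4, 4, 2)), (1, 1, 1), SHBasis(2))

    def test_round_trip_identity(self, rng):
        img = self._image(rng)
        scales = tr.compute_normalization([img])
        normed, n_clip = tr.normalize_intensity(img, scales)
        assert n_clip == 0
        back = tr.denormalize_intensity(normed, scales)
        assert np.abs(back.coefficients - img.coefficients).max() < 1e-7

    def test_scale_only_mapping_keeps_zero(self, rng):
        scales = np.full(6, 2.0)
        zero = SHImage(np.zeros((6, 2, 2, 2)), (1, 1, 1), SHBasis(2))
        normed, _ = tr.normalize_intensity(zero, scales)
        assert np.all(normed.coefficients == 0.0)

    def test_channel_max_maps_to_at_most_one(self, rng):
        img = self._image(rng)
        scales = tr.compute_normalization([img])
        normed, _ = tr.normalize_intensity(img, scales)
        assert np.abs(normed.coefficients).max() <= 1.0

    def test_out_of_range_values_clipped_and_counted(self, rng):
        img = self._image(rng)
        scales = np.full(6, 1e-3)
        normed, n_clip = tr.normalize_intensity(img, scales)
        assert n_clip > 0
        assert np.abs(normed.coefficients).max() <= 1.0

    def test_non_positive_scale_rejected(self, rng):
        with pytest.raises(ValueError):
            tr.normalize_intensity(self._image(rng), np.zeros(6))


class TestConfigValidation:
    def test_defaults_match_training_recipe(self):
        cfg = tr.TrainConfig()
        assert (cfg.lr, cfg.batch_size, cfg.lambda_l1, cfg.kappa_gp) \
            == (1e-4, 6, 50000.0, 10.0)
        assert (cfg.steps_e, cfg.steps_g, cfg.steps_d, cfg.steps_cd) == (1, 2, 4, 1)

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            tr.TrainConfig(lambda_l1=-1.0)
        with pytest.raises(ValueError):
            tr.TrainConfig(batch_size=0)


class TestTrainingLoop:
    def _fast_cfg(self, epochs, seed=0):
        return tr.TrainConfig(epochs=epochs, seed=seed, batch_size=2)

    def test_optimizer_step_ledger_and_determinism(self, tiny_train_cohort):
        runs = []
        for _ in range(2):
            state = tr.train(self._fast_cfg(2, seed=5), tiny_train_cohort,
                             scale=TINY_SCALE)
            runs.append(state)
        k = 2
        assert runs[0].step_counts == {"E": k, "G": 2 * k, "D": 4 * k, "CD": k}
        assert runs[0].history == runs[1].history  # bit-identical trajectories
        for (_, a), (_, b) in zip(runs[0].nets["generator"].parameters(),
                                  runs[1].nets["generator"].parameters()):
            assert np.array_equal(a.data, b.data)

    def test_resume_reproduces_uninterrupted_run(self, tiny_train_cohort, tmp_path):
        full = tr.train(self._fast_cfg(4, seed=9), tiny_train_cohort, scale=TINY_SCALE)
        half = tr.train(self._fast_cfg(2, seed=9), tiny_train_cohort,
                        scale=TINY_SCALE, out_dir=str(tmp_path))
        resumed = tr.load_checkpoint(str(tmp_path))
        resumed.config.epochs = 4
        resumed = tr.train(resumed.config, tiny_train_cohort, state=resumed)
        assert resumed.history == full.history
        for (_, a), (_, b) in zip(full.nets["discriminator"].parameters(),
                                  resumed.nets["discriminator"].parameters()):
            assert np.array_equal(a.data, b.data)

    def test_zero_epochs_leaves_networks_at_init(self, tiny_train_cohort):
        state = tr.train(self._fast_cfg(0, seed=3), tiny_train_cohort, scale=TINY_SCALE)
        from fodgan.networks import all_paper_specs, build
        fresh = {name: build(spec, seed=3 + i) for i, (name, spec) in
                 enumerate(sorted(all_paper_specs(TINY_SCALE).items()))}
        for name, net in state.nets.items():
            for (_, a), (_, b) in zip(net.parameters(), fresh[name].parameters()):
                assert np.array_equal(a.data, b.data)

    def test_non_finite_loss_aborts(self, tiny_train_cohort):
        state = tr.train(self._fast_cfg(0, seed=1), tiny_train_cohort, scale=TINY_SCALE)
        bad = np.stack([im.coefficients for im in tiny_train_cohort[:2]]).astype(np.float32)
        bad[0, 0, 0, 0, 0] = np.nan
        source = tr.ArrayDataSource(bad)
        with pytest.raises(tr.TrainingDiverged):
            tr.epoch_step(state, source, state.config)

    def test_vae_limit_reconstruction_improves(self, tiny_train_cohort):
        # dominant L1 weight: two-subject cohort behaves like an autoencoder
        pair = tiny_train_cohort[:2]
        cfg = tr.TrainConfig(epochs=1, seed=2, batch_size=2, lambda_l1=50000.0)
        state = tr.train(cfg, pair, scale=TINY_SCALE)
        before = tr.reconstruction_l1(state, pair)
        state.config.epochs = 8
        state = tr.train(state.config, pair, state=state)
        after = tr.reconstruction_l1(state, pair)
        assert after < before

    def test_cohort_mismatching_model_dims_rejected(self, rng):
        img = SHImage(rng.standard_normal((28, 8, 8, 4)), (1, 1, 1), SHBasis(6))
        with pytest.raises(ValueError, match="contract"):
            tr.train(tr.TrainConfig(epochs=1), [img], scale=TINY_SCALE)
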