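"""CVAE: loss arithmetic, training behavior, sampling-based prediction."""

import numpy as np
import pytest

from spfp.cvae import (
    CVAEConfig,
    CVAERegressor,
    TrainedCVAE,
    elbo_loss,
    fit_matrices,
    tune,
)
from spfp.encoding import PotencyModuleSpec, encode_potency

SMALL = CVAEConfig(
    hidden_sizes=(48, 24),
    latent_dim=8,
    batch_size=32,
    learning_rate=0.001,
    max_epochs=40,
    early_stop_patience=12,
    lr_patience=6,
    seed=0,
)


def _matrices(ac, spec=PotencyModuleSpec()):
    X = np.vstack([encode_potency(v, spec) for v in ac.potencies]).astype(float)
    C = ac.fingerprints().astype(float)
    return X, C, spec


class TestElboLoss:
    def test_standard_normal_posterior_has_zero_kl(self):
        x = np.ones((1, 4))
        p = np.full((1, 4), 0.9)
        with_kl = elbo_loss(x, p, np.zeros((1, 2)), np.zeros((1, 2)), beta=5.0)
        bce_only = elbo_loss(x, p, np.zeros((1, 2)), np.zeros((1, 2)), beta=0.0)
        assert with_kl == pytest.approx(bce_only)

    def test_uniform_probability_cross_entropy(self):
        """p = 0.5 everywhere gives BCE = L ln 2 regardless of the target."""
        L = 100
        for x in (np.zeros((1, L)), np.ones((1, L))):
            loss = elbo_loss(x, np.full((1, L), 0.5), np.zeros((1, 1)), np.zeros((1, 1)))
            assert loss == pytest.approx(L * np.log(2), rel=1e-9)

    def test_hand_computed_four_bit_case(self):
        x = np.array([[1, 1, 0, 0]], dtype=float)
        p = np.array([[0.9, 0.8, 0.2, 0.1]])
        expected = -(np.log(0.9) + np.log(0.8) + np.log(0.8) + np.log(0.9))
        assert elbo_loss(x, p, np.zeros((1, 1)), np.zeros((1, 1)), beta=1.0) == pytest.approx(
            expected, rel=1e-9
        )

    def test_saturated_probability_stays_finite(self):
        loss = elbo_loss(np.ones((1, 2)), np.zeros((1, 2)), np.zeros((1, 1)), np.zeros((1, 1)))
        assert np.isfinite(loss)

    def test_kl_nonnegative_for_random_posteriors(self, rng):
        for _ in range(20):
            mu = rng.normal(size=(3, 5))
            logvar = rng.normal(size=(3, 5))
            kl_part = elbo_loss(
                np.zeros((3, 2)), np.full((3, 2), 0.5), mu, logvar, beta=1.0
            ) - elbo_loss(np.zeros((3, 2)), np.full((3, 2), 0.5), mu, logvar, beta=0.0)
            assert kl_part >= -1e-9


class TestFit:
    def test_loss_decreases_and_history_recorded(self, small_class):
        X, C, spec = _matrices(small_class)
        model = fit_matrices(X, C, spec, SMALL)
        assert model.history[-1]["train_loss"] <= model.history[0]["train_loss"]
        assert {"epoch", "train_loss", "val_loss", "lr"} <= set(model.history[0])

    def test_seeded_reproducibility(self, small_class):
        X, C, spec = _matrices(small_class)
        m1 = fit_matrices(X, C, spec, SMALL)
        m2 = fit_matrices(X, C, spec, SMALL)
        assert m1.history[-1]["train_loss"] == pytest.approx(
            m2.history[-1]["train_loss"], abs=0
        )

    def test_constant_potency_class_recovers_prefix_pattern(self, small_class):
        """All compounds share one potency: reconstructions converge to
        that single prefix pattern (>= 95% per-bit agreement)."""
        spec = PotencyModuleSpec()
        C = small_class.fingerprints().astype(float)
        X = np.vstack([encode_potency(7.5, spec)] * len(small_class)).astype(float)
        model = fit_matrices(X, C, spec, SMALL)
        prob = model.reconstruct(X, C)
        agreement = ((prob >= 0.5) == (X >= 0.5)).mean()
        assert agreement >= 0.95

    def test_reconstruction_of_training_modules(self, noiseless_class_with_truth):
        """On a noiseless class, encode -> model -> binarize recovers at
        least 90% of the potency-module bits."""
        ac, _ = noiseless_class_with_truth
        X, C, spec = _matrices(ac)
        model = fit_matrices(X, C, spec, SMALL)
        prob = model.reconstruct(X, C)
        assert ((prob >= 0.5) == (X >= 0.5)).mean() >= 0.90

    def test_divergence_raises_with_epoch(self, small_class):
        from spfp.cvae import TrainingDivergedError

        X, C, spec = _matrices(small_class)
        bad = CVAEConfig(
            hidden_sizes=(16,), latent_dim=4, learning_rate=1e200, batch_size=32, max_epochs=5
        )
        with np.errstate(over="ignore", invalid="ignore"):
            with pytest.raises(TrainingDivergedError, match="epoch"):
                fit_matrices(X, C, spec, bad)

    def test_higher_beta_pulls_posterior_toward_prior(self, small_class):
        X, C, spec = _matrices(small_class)
        mean_abs_mu = []
        for beta in (1.0, 2.0, 8.0):
            cfg = CVAEConfig(
                hidden_sizes=(32, 16),
                latent_dim=8,
                batch_size=32,
                max_epochs=25,
                beta=beta,
                seed=0,
            )
            m = fit_matrices(X, C, spec, cfg)
            mu, _ = m.encode(X, C)
            mean_abs_mu.append(np.abs(mu).mean())
        assert mean_abs_mu[0] >= mean_abs_mu[-1]


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self, small_class):
        X, C, spec = _matrices(small_class)
        return fit_matrices(X, C, spec, SMALL), C

    def test_prediction_within_open_range(self, trained):
        model, C = trained
        res = model.predict(C[0])
        assert 5.0 < res.predicted_pIC50 < 11.0
        assert res.interval_halfwidth == pytest.approx(0.03)
        assert res.attempts >= 1

    def test_valid_single_bit_module_decodes_to_5_03(self, trained):
        """A sampled module with one leading bit decodes to the center
        of the lowest interval."""
        model, _ = trained
        r = model.spec.resolution
        assert model.spec.range_low + r / 2 == pytest.approx(5.03)

    def test_batch_matches_sequential(self, trained):
        model, C = trained
        vals_b, valid_b, _ = model.predict_batch(C[:5], np.random.default_rng(42))
        assert vals_b.shape == (5,)
        assert np.all((vals_b > 5.0) & (vals_b < 11.0))

    def test_fallback_on_exhaustion_is_flagged_invalid(self, trained):
        model, C = trained
        from dataclasses import replace

        starved = replace(model.config, max_sampling_attempts=0)
        hobbled = TrainedCVAE(starved, model.spec, model.encoder, model.decoder)
        vals, valid, attempts = hobbled.predict_batch(C[:3], np.random.default_rng(0))
        assert not valid.any()
        assert np.all((vals > 5.0) & (vals < 11.0))


class TestTune:
    def test_singleton_grid_returns_that_config(self, small_class):
        X, C, spec = _matrices(small_class)
        base = CVAEConfig(hidden_sizes=(16,), latent_dim=4, batch_size=32, max_epochs=5)
        best, table = tune(
            X[:60], C[:60], spec, grid={"latent_dim": [4]}, base_config=base, n_folds=3
        )
        assert best.latent_dim == 4
        assert len(table) == 1 and np.isfinite(table[0]["cv_mae"])

    def test_degenerate_config_never_selected(self, small_class):
        X, C, spec = _matrices(small_class)
        base = CVAEConfig(hidden_sizes=(24,), latent_dim=4, batch_size=32, max_epochs=12)
        best, table = tune(
            X[:80],
            C[:80],
            spec,
            grid={"learning_rate": [10.0, 0.001]},
            base_config=base,
            n_folds=3,
        )
        scores = {row["learning_rate"]: row["cv_mae"] for row in table}
        assert best.learning_rate == 0.001
        assert scores[0.001] < scores[10.0]

    def test_empty_grid_rejected(self, small_class):
        X, C, spec = _matrices(small_class)
        with pytest.raises(ValueError):
            tune(X, C, spec, grid={})


def test_regressor_interface_and_checkpoint(tmp_path, small_class):
    reg = CVAERegressor(SMALL)
    fps, y = small_class.fingerprints(), small_class.potencies
    reg.fit(fps, y)
    pred = reg.predict(fps[:10])
    assert pred.shape == (10,)
    assert np.all(np.isfinite(pred))

    path = tmp_path / "model.zip"
    reg.model.save(path)
    loaded = TrainedCVAE.load(path)
    p1 = loaded.predict_batch(fps[:5].astype(float), np.random.default_rng(3))[0]
    p2 = reg.model.predict_batch(fps[:5].astype(float), np.random.default_rng(3))[0]
    assert np.allclose(p1, p2)


def test_finite_predictions_for_degenerate_fingerprints(small_class):
    """All-zero and all-one structure modules still yield finite decoded
    potencies."""
    reg = CVAERegressor(SMALL)
    reg.fit(small_class.fingerprints(), small_class.potencies)
    queries = np.vstack([np.zeros(2048), np.ones(2048)])
    pred = reg.predict(queries)
    assert np.all(np.isfinite(pred))
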