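"""RR-BLUP/GBLUP equivalences, Gibbs-sampler oracles, prediction, accuracy."""

import numpy as np
import pytest

from panelsim.trait_model import build_architecture, simulate_trait
from panelsim.wgr_models import (
    FittedWGR,
    MCMCSettings,
    accuracy,
    fit_bayesB,
    fit_bayesC,
    fit_rrblup,
    predict_genetic_values,
)

from conftest import random_inbred_panel


def ridge_oracle(X, y, lam):
    """Direct p-space ridge solution at fixed lambda with GLS intercept."""
    Z = X - X.mean(axis=0)
    n = len(y)
    A = Z @ Z.T + lam * np.eye(n)
    ones = np.ones(n)
    Ainv_y = np.linalg.solve(A, y)
    Ainv_1 = np.linalg.solve(A, ones)
    mu = ones @ Ainv_y / (ones @ Ainv_1)
    u = np.linalg.solve(Z.T @ Z + lam * np.eye(Z.shape[1]), Z.T @ (y - mu))
    return mu, u


def gblup_oracle_predictions(X_tr, y, X_new, lam):
    """Kernel (GBLUP) formulation: g_new = K_new,tr (K + lam I)^-1 (y - mu)."""
    c = X_tr.mean(axis=0)
    Z, Znew = X_tr - c, X_new - c
    K = Z @ Z.T
    n = len(y)
    A = K + lam * np.eye(n)
    ones = np.ones(n)
    mu = ones @ np.linalg.solve(A, y) / (ones @ np.linalg.solve(A, ones))
    return Znew @ Z.T @ np.linalg.solve(A, y - mu)


@pytest.fixture
def toy_regression():
    rng = np.random.default_rng(8)
    X = (2 * (rng.random((40, 15)) < rng.uniform(0.2, 0.8, 15))).astype(float)
    b = rng.standard_normal(15)
    y = X @ b + rng.standard_normal(40)
    return X, y


class TestRRBLUP:
    def test_constant_phenotype_zero_effects(self, toy_regression):
        X, _ = toy_regression
        with pytest.warns(UserWarning, match="constant"):
            fit = fit_rrblup(X, np.full(X.shape[0], 3.5))
        assert fit.intercept == 3.5
        assert np.all(fit.effects == 0)

    def test_fixed_lambda_matches_direct_inverse(self, toy_regression):
        X, y = toy_regression
        fit = fit_rrblup(X, y, lambda_=1.0)
        mu, u = ridge_oracle(X, y, 1.0)
        assert fit.intercept == pytest.approx(mu, abs=1e-8)
        assert np.allclose(fit.effects, u, atol=1e-8)

    def test_reml_predictions_match_gblup_kernel(self, toy_regression):
        """The marker-effect and kernel formulations of ridge BLUP are the
        same model; predictions must agree to numerical precision."""
        X, y = toy_regression
        rng = np.random.default_rng(1)
        X_new = (2 * (rng.random((15, 15)) < 0.5)).astype(float)
        fit = fit_rrblup(X, y)
        lam = fit.sampler_meta["lambda"]
        pred = predict_genetic_values(fit, X_new)
        oracle = gblup_oracle_predictions(X, y, X_new, lam)
        assert np.allclose(pred, oracle, atol=1e-6)

    @pytest.mark.parametrize("n,p,seed", [(30, 60, 0), (80, 40, 1), (100, 500, 2)])
    def test_gblup_identity_on_random_instances(self, n, p, seed):
        rng = np.random.default_rng(seed)
        X = (2 * (rng.random((n, p)) < rng.uniform(0.1, 0.9, p))).astype(float)
        y = X @ rng.standard_normal(p) * 0.1 + rng.standard_normal(n)
        fit = fit_rrblup(X, y)
        pred = predict_genetic_values(fit, X)
        oracle = gblup_oracle_predictions(X, y, X, fit.sampler_meta["lambda"])
        assert np.allclose(pred, oracle, atol=1e-6)

    def test_duplicated_columns_split_effects_keep_predictions(self, toy_regression):
        """Ridge splits the effect of a duplicated column in half (REML
        halves the per-marker variance), leaving predictions unchanged."""
        X, y = toy_regression
        fit1 = fit_rrblup(X, y)
        fit2 = fit_rrblup(np.hstack([X, X]), y)
        p = X.shape[1]
        assert np.allclose(fit2.effects[:p], fit1.effects / 2, atol=1e-5)
        pred1 = predict_genetic_values(fit1, X)
        pred2 = predict_genetic_values(fit2, np.hstack([X, X]))
        assert np.allclose(pred1, pred2, atol=1e-6)

    def test_variance_components_recovered_in_large_sample(self):
        """REML sigma_e^2 should track the simulation truth."""
        rng = np.random.default_rng(5)
        n, p = 300, 100
        X = (2 * (rng.random((n, p)) < 0.5)).astype(float)
        u = rng.standard_normal(p) * 0.2
        y = X @ u + rng.standard_normal(n)
        fit = fit_rrblup(X, y)
        assert fit.residual_variance == pytest.approx(1.0, rel=0.35)

    def test_dimension_mismatch_rejected(self, toy_regression):
        X, y = toy_regression
        with pytest.raises(ValueError, match="dimension"):
            fit_rrblup(X, y[:-1])


class TestBayesSamplers:
    def test_pi_one_gives_empty_model(self, toy_regression):
        X, y = toy_regression
        st = MCMCSettings(n_iter=300, burn_in=50, seed=0)
        for fitter in (fit_bayesB, fit_bayesC):
            fit = fitter(X, y, st, pi_zero=1.0, update_pi=False)
            assert np.all(fit.effects == 0)
            pred = predict_genetic_values(fit, X)
            assert np.allclose(pred, 0.0)

    def test_seed_determinism(self, toy_regression):
        X, y = toy_regression
        st = MCMCSettings(n_iter=400, burn_in=100, seed=123)
        for fitter in (fit_bayesB, fit_bayesC):
            a, b = fitter(X, y, st), fitter(X, y, st)
            assert np.array_equal(a.effects, b.effects)
            assert a.residual_variance == b.residual_variance

    def test_single_locus_conjugate_posterior(self):
        """With one column, pi=0 and both variances fixed, the Gibbs chain
        samples the exact conjugate normal posterior; its mean must match
        the closed form within Monte-Carlo error."""
        rng = np.random.default_rng(3)
        x = (2 * (rng.random(60) < 0.4)).astype(float)[:, None]
        y = 0.8 * x[:, 0] + rng.standard_normal(60)
        var_b, var_e = 2.0, 1.0
        st = MCMCSettings(n_iter=6000, burn_in=1000, thin=10, seed=7)
        fit = fit_bayesC(
            x,
            y,
            st,
            pi_zero=0.0,
            update_pi=False,
            fix_marker_variance=var_b,
            fix_residual_variance=var_e,
        )
        xc = x[:, 0] - x[:, 0].mean()
        # closed form: precision-weighted mean of the centered regression,
        # with the intercept integrated over its flat posterior (the chain
        # samples mu around the residual mean, inflating rhs noise only)
        prec = xc @ xc / var_e + 1.0 / var_b
        expect = (xc @ (y - y.mean()) / var_e) / prec
        mc_se = fit.effect_posterior_sd[0] / np.sqrt(fit.sampler_meta["n_samples"])
        assert fit.effects[0] == pytest.approx(expect, abs=3 * mc_se + 1e-3)

    def test_pi_zero_fixed_variances_matches_ridge(self):
        """pi=0 with fixed variances is Bayesian ridge; posterior-mean
        effects must track the deterministic ridge solution."""
        rng = np.random.default_rng(9)
        n, p = 80, 50
        X = (2 * (rng.random((n, p)) < rng.uniform(0.2, 0.8, p))).astype(float)
        y = X @ (rng.standard_normal(p) * 0.3) + rng.standard_normal(n)
        var_b, var_e = 0.3**2, 1.0
        lam = var_e / var_b
        st = MCMCSettings(n_iter=4000, burn_in=1000, thin=3, seed=11)
        fit = fit_bayesC(
            X,
            y,
            st,
            pi_zero=0.0,
            update_pi=False,
            fix_marker_variance=var_b,
            fix_residual_variance=var_e,
        )
        _, u = ridge_oracle(X, y, lam)
        assert np.corrcoef(fit.effects, u)[0, 1] > 0.99

    def test_bayesB_shrinks_large_effect_less_than_ridge(self):
        """One huge effect among nulls: the heavy-tailed per-locus prior
        should shrink it less than the common-variance ridge."""
        rng = np.random.default_rng(13)
        n, p = 100, 30
        X = (2 * (rng.random((n, p)) < 0.5)).astype(float)
        b = np.zeros(p)
        b[4] = 3.0
        y = X @ b + rng.standard_normal(n)
        st = MCMCSettings(n_iter=2000, burn_in=500, seed=2)
        bb = fit_bayesB(X, y, st, pi_zero=0.0, update_pi=False)
        rr = fit_rrblup(X, y)
        assert abs(bb.effects[4]) > abs(rr.effects[4])

    def test_bayesB_recovers_effects_at_high_heritability(self):
        """All-QTL panel, h2=0.9, n=400: posterior-mean effects should
        correlate strongly with the simulated truth."""
        panel = random_inbred_panel(400, 50, seed=21)
        arch = build_architecture(panel, 50, seed=3)
        trait = simulate_trait(panel, arch, h2=0.9, seed=4)
        X = panel.dosages[:, arch.qtl_indices].astype(float)
        st = MCMCSettings(n_iter=1500, burn_in=400, seed=5)
        fit = fit_bayesB(X, trait.phenotypes, st)
        order = np.argsort(arch.qtl_indices)
        assert np.corrcoef(fit.effects, arch.effects[order])[0, 1] > 0.9

    def test_monomorphic_columns_get_zero_effect(self, toy_regression):
        X, y = toy_regression
        X = np.hstack([X, np.full((X.shape[0], 1), 2.0)])
        st = MCMCSettings(n_iter=300, burn_in=100, seed=0)
        with pytest.warns(UserWarning, match="monomorphic"):
            fit = fit_bayesC(X, y, st)
        assert fit.effects[-1] == 0.0

    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError, match="burn_in"):
            MCMCSettings(n_iter=100, burn_in=100)
        with pytest.raises(ValueError, match="prior_df"):
            MCMCSettings(prior_df=2.0)


class TestPredictAccuracy:
    def test_training_predictions_centered(self, toy_regression):
        X, y = toy_regression
        fit = fit_rrblup(X, y)
        pred = predict_genetic_values(fit, X)
        assert abs(pred.mean()) < 1e-8

    def test_hand_computed_prediction(self):
        fit = FittedWGR(
            model="rrblup",
            intercept=0.0,
            effects=np.array([0.5, -1.0]),
            marker_variance=1.0,
            residual_variance=1.0,
            column_centers=np.array([1.0, 1.0]),
        )
        pred = predict_genetic_values(fit, np.array([[2.0, 0.0]]))
        assert pred[0] == pytest.approx(1.5)

    def test_column_mismatch_rejected(self, toy_regression):
        X, y = toy_regression
        fit = fit_rrblup(X, y)
        with pytest.raises(ValueError, match="columns"):
            predict_genetic_values(fit, X[:, :-1])

    def test_accuracy_examples(self):
        t = np.array([1.0, 2.0, 4.0, 3.0])
        assert accuracy(t, t) == pytest.approx(1.0)
        assert accuracy(-t, t) == pytest.approx(-1.0)
        assert accuracy([1, 2, 3, 4], [1, 2, 4, 3]) == pytest.approx(0.8)

    def test_accuracy_affine_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.standard_normal(50), rng.standard_normal(50)
        assert accuracy(2.5 * a + 7, b) == pytest.approx(accuracy(a, b))

    def test_accuracy_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            accuracy([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
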