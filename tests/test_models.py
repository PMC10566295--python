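import numpy as np
import pytest

from husk_gs import (
    BayesianAlphabetRegressor,
    GenotypeMatrix,
    RRBLUP,
    fit_bayes,
    fit_rrblup,
    predict_gebv,
)


def _mk(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix([f"L{i}" for i in range(n)],
                          [f"m{j}" for j in range(m)], dosages,
                          ["1"] * m, range(1, m + 1), ["A"] * m, ["T"] * m)


@pytest.fixture(scope="module")
def ridge_friendly():
    """Polygenic trait on a random panel, h2 about 0.5."""
    rng = np.random.default_rng(7)
    n, m = 150, 300
    X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
    eff = rng.normal(0, 1 / np.sqrt(m), m)
    tbv = X @ eff
    y = tbv + rng.normal(0, tbv.std(), n)
    return X, y, tbv


class TestRRBLUP:
    def test_constant_response(self):
        X = np.random.default_rng(0).binomial(2, 0.5, (10, 5)).astype(float)
        m = RRBLUP().fit(X, np.full(10, 4.2))
        assert np.all(m.coef_ == 0)
        np.testing.assert_allclose(m.predict(X), 4.2)

    def test_two_line_fixed_lambda_worked_example(self):
        m = RRBLUP(lambda_=1.0).fit(np.array([[1.0], [-1.0]]), np.array([1.0, -1.0]))
        assert m.coef_[0] == pytest.approx(2 / 3)

    def test_fixed_lambda_matches_primal_ridge(self):
        rng = np.random.default_rng(1)
        for lam in (0.5, 1.0, 10.0):
            X = rng.normal(size=(50, 20))
            y = rng.normal(size=50)
            m = RRBLUP(lambda_=lam).fit(X, y)
            Zc = X - X.mean(axis=0)
            ref = np.linalg.solve(Zc.T @ Zc + lam * np.eye(20),
                                  Zc.T @ (y - m.intercept_))
            np.testing.assert_allclose(m.coef_, ref, atol=1e-8)

    def test_reml_optimum_beats_lambda_grid(self, ridge_friendly):
        X, y, _ = ridge_friendly
        m = RRBLUP().fit(X, y)
        best = m.reml_loglik(m.lambda_opt_)
        for lam in np.exp(np.linspace(-10, 10, 50)):
            assert best >= m.reml_loglik(lam) - 1e-6

    def test_recovers_signal(self, ridge_friendly):
        X, y, tbv = ridge_friendly
        m = RRBLUP().fit(X, y)
        assert np.corrcoef(m.predict(X), tbv)[0, 1] > 0.7

    def test_too_few_lines(self):
        with pytest.raises(ValueError):
            RRBLUP().fit(np.ones((2, 3)), np.array([1.0, 2.0]))

    def test_missing_dosages_rejected(self):
        X = np.array([[0.0, np.nan], [1, 1], [2, 0]])
        with pytest.raises(ValueError, match="impute"):
            RRBLUP().fit(X, np.array([1.0, 2, 3]))


class TestBayesianAlphabet:
    def test_seed_determinism(self, ridge_friendly):
        X, y, _ = ridge_friendly
        kw = dict(n_iter=300, burnin=100, random_state=11)
        a = BayesianAlphabetRegressor("BayesB", **kw).fit(X, y)
        b = BayesianAlphabetRegressor("BayesB", **kw).fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)
        assert a.intercept_ == b.intercept_

    @pytest.mark.parametrize("model", ["BayesA", "BayesB", "BayesC", "BL", "BRR"])
    def test_all_models_recover_signal(self, ridge_friendly, model):
        X, y, tbv = ridge_friendly
        m = BayesianAlphabetRegressor(model, n_iter=800, burnin=300, thin=2,
                                      random_state=2).fit(X, y)
        assert np.corrcoef(m.predict(X), tbv)[0, 1] > 0.6

    def test_residual_variance_recovery(self):
        # conjugate-friendly: strong signal, known noise variance
        rng = np.random.default_rng(13)
        n, m = 250, 80
        X = rng.binomial(2, 0.5, (n, m)).astype(float)
        eff = rng.normal(0, 0.15, m)
        sigma_e = 1.0
        y = X @ eff + rng.normal(0, sigma_e, n)
        fit = BayesianAlphabetRegressor("BRR", n_iter=2000, burnin=500,
                                        random_state=3).fit(X, y)
        assert abs(fit.posterior_["sigma_e2"] - sigma_e ** 2) < 0.2 * sigma_e ** 2

    def test_invalid_params(self, ridge_friendly):
        X, y, _ = ridge_friendly
        with pytest.raises(ValueError):
            BayesianAlphabetRegressor("BayesZ").fit(X, y)
        with pytest.raises(ValueError):
            BayesianAlphabetRegressor("BRR", n_iter=100, burnin=100).fit(X, y)
        with pytest.raises(ValueError):
            BayesianAlphabetRegressor("BRR", thin=0).fit(X, y)
        with pytest.raises(ValueError):
            BayesianAlphabetRegressor("BayesC", pi=1.5).fit(X, y)


class TestPredictGEBV:
    def test_training_panel_reproduces_fitted_values(self, ridge_friendly):
        X, y, _ = ridge_friendly
        g = _mk(X)
        fit = fit_rrblup(g, y)
        res = predict_gebv(fit, g)
        est = RRBLUP().fit(X, y)
        np.testing.assert_allclose(res.gebv, est.predict(X), atol=1e-10)

    def test_line_at_training_centers_scores_intercept(self, ridge_friendly):
        X, y, _ = ridge_friendly
        g = _mk(X)
        fit = fit_rrblup(g, y)
        center_line = GenotypeMatrix(["C"], g.marker_ids,
                                     fit.centering[None, :].clip(0, 2),
                                     g.chrom, g.pos, g.ref, g.alt)
        # use the exact centers (may be fractional, still in [0,2])
        center_line.dosages[:] = fit.centering
        res = predict_gebv(fit, center_line)
        assert res.gebv[0] == pytest.approx(fit.intercept)

    def test_effect_doubling_is_linear(self, ridge_friendly):
        X, y, _ = ridge_friendly
        g = _mk(X)
        fit = fit_rrblup(g, y)
        base = predict_gebv(fit, g).gebv
        fit.marker_effects = fit.marker_effects.copy()
        k = 3
        contrib = (X[:, k] - fit.centering[k]) * fit.marker_effects[k]
        fit.marker_effects[k] *= 2
        doubled = predict_gebv(fit, g).gebv
        np.testing.assert_allclose(doubled - base, contrib, atol=1e-10)

    def test_marker_mismatch_rejected(self, ridge_friendly):
        X, y, _ = ridge_friendly
        g = _mk(X)
        fit = fit_rrblup(g, y)
        g_sub = g.subset(marker_idx=np.arange(10))
        with pytest.raises(ValueError, match="marker"):
            predict_gebv(fit, g_sub)

    def test_fit_bayes_roundtrip_serialization(self, ridge_friendly, tmp_path):
        from husk_gs.models import GSFit

        X, y, _ = ridge_friendly
        g = _mk(X)
        fit = fit_bayes(g, y, model="BRR", iters=200, burnin=50, seed=4)
        path = tmp_path / "fit.json"
        fit.to_json(str(path))
        back = GSFit.from_json(str(path))
        np.testing.assert_allclose(back.marker_effects, fit.marker_effects)
        assert back.model == "BRR"
        r1 = predict_gebv(fit, g).gebv
        r2 = predict_gebv(back, g).gebv
        np.testing.assert_allclose(r1, r2)
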