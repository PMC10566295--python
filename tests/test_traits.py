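import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from husk_gs import (
    BlupResult,
    HuskMeasurement,
    MoistureSeries,
    VarianceComponents,
    compute_auddc,
    compute_hti,
    correlation_test,
    estimate_heritability,
    fit_environment_blup,
)


class TestHTI:
    @pytest.mark.parametrize("loose,tight,expected", [
        (12.0, 12.0, 0.0),
        (10.0, 8.0, 20.0),
        (20.0, 15.0, 25.0),
    ])
    def test_worked_values(self, loose, tight, expected):
        assert compute_hti(HuskMeasurement("L1", loose, tight)) == pytest.approx(expected)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            HuskMeasurement("L1", 0.0, 0.0)
        with pytest.raises(ValueError, match="exceeds"):
            HuskMeasurement("L1", 10.0, 11.0)

    @given(loose=st.floats(1.0, 50.0), frac=st.floats(0.0, 0.95))
    @settings(max_examples=50, derandomize=True)
    def test_range(self, loose, frac):
        hti = compute_hti(HuskMeasurement("L", loose, loose * (1 - frac)))
        assert 0.0 <= hti <= 100.0


class TestAUDDC:
    def test_constant_reading_over_study_days(self):
        s = MoistureSeries("L", [34, 40, 46, 52, 58], [3.0] * 5)
        assert compute_auddc(s) == pytest.approx(24 * 3.0)

    def test_small_worked_example(self):
        s = MoistureSeries("L", [0, 1, 2], [2, 4, 6])
        assert compute_auddc(s) == pytest.approx(8.0)

    def test_breakpoint_on_linear_segment_is_neutral(self):
        a = MoistureSeries("L", [0, 2], [1.0, 5.0])
        b = MoistureSeries("L", [0, 1, 2], [1.0, 3.0, 5.0])
        assert compute_auddc(a) == pytest.approx(compute_auddc(b))

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, derandomize=True)
    def test_linear_in_readings(self, scale):
        days = [34, 40, 46, 52, 58]
        base = np.array([50, 45, 38, 30, 25.0])
        a = compute_auddc(MoistureSeries("L", days, base))
        b = compute_auddc(MoistureSeries("L", days, scale * base))
        assert b == pytest.approx(scale * a)

    def test_invalid_series(self):
        with pytest.raises(ValueError):
            MoistureSeries("L", [34], [1.0])
        with pytest.raises(ValueError, match="increasing"):
            MoistureSeries("L", [34, 34], [1.0, 2.0])


class TestHeritability:
    def test_plug_in_arithmetic(self):
        v = VarianceComponents(2.0, 3.0, 6.0, n_env=3, n_rep=2, mu=0.0)
        assert estimate_heritability(v) == pytest.approx(0.5)

    def test_zero_genetic_variance(self):
        v = VarianceComponents(0.0, 1.0, 1.0, 2, 2, 0.0)
        assert estimate_heritability(v) == 0.0

    def test_all_zero_raises(self):
        v = VarianceComponents(0.0, 0.0, 0.0, 2, 2, 0.0)
        with pytest.raises(ValueError):
            estimate_heritability(v)

    @given(sg=st.floats(0.1, 5.0), bump=st.floats(0.1, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_monotone_in_components(self, sg, bump):
        base = VarianceComponents(sg, 1.0, 1.0, 3, 2, 0.0)
        h0 = estimate_heritability(base)
        assert estimate_heritability(
            VarianceComponents(sg + bump, 1.0, 1.0, 3, 2, 0.0)) > h0
        assert estimate_heritability(
            VarianceComponents(sg, 1.0 + bump, 1.0, 3, 2, 0.0)) < h0
        assert estimate_heritability(
            VarianceComponents(sg, 1.0, 1.0 + bump, 3, 2, 0.0)) < h0


class TestCorrelationTest:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlation_test(x, x)[0] == pytest.approx(1.0)
        assert correlation_test(x, -x)[0] == pytest.approx(-1.0)

    def test_null_is_calibrated(self):
        rng = np.random.default_rng(3)
        rs, ps = [], []
        for _ in range(40):
            x, y = rng.normal(size=(2, 1000))
            r, p = correlation_test(x, y)
            rs.append(r)
            ps.append(p)
        assert max(abs(r) for r in rs) < 0.12
        # p approximately uniform: mean near 0.5, spread over [0, 1]
        assert 0.3 < np.mean(ps) < 0.7

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            correlation_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestEnvironmentBlup:
    def test_constant_observations(self):
        rows = [{"line_id": f"L{i}", "environment": e, "replicate": r, "value": 7.0}
                for i in range(5) for e in ("E1", "E2") for r in ("R1", "R2")]
        res = fit_environment_blup(pd.DataFrame(rows))
        np.testing.assert_allclose(res.blup, 7.0)
        assert res.components.sigma2_g == 0.0

    def test_balanced_recovery(self, balanced_pheno):
        pheno, true_f = balanced_pheno
        res = fit_environment_blup(pheno)
        aligned = true_f.loc[list(res.line_ids)].to_numpy()
        r = np.corrcoef(res.blup, aligned)[0, 1]
        assert r > 0.85

    def test_blup_shrinks_toward_mean(self, balanced_pheno):
        pheno, _ = balanced_pheno
        res = fit_environment_blup(pheno)
        raw = pheno.groupby("line_id")["value"].mean().loc[list(res.line_ids)]
        assert np.var(res.blup) < np.var(raw.to_numpy())
        # random effects centered
        assert abs(np.mean(res.blup - res.components.mu)) < 0.15

    def test_single_env_single_rep_no_noise_limit(self):
        # one observation per line: all variance attributed to genetics,
        # so BLUPs equal the raw values
        vals = [3.0, 5.0, 9.0, 1.0]
        p = pd.DataFrame({"line_id": [f"L{i}" for i in range(4)],
                          "environment": "E1", "replicate": "R1",
                          "value": vals})
        with pytest.warns(UserWarning, match="single environment"):
            res = fit_environment_blup(p)
        order = np.argsort(res.line_ids)
        np.testing.assert_allclose(np.sort(res.blup), np.sort(vals))
        assert res.components.sigma2_e == 0.0

    def test_unbalanced_fit_runs(self, balanced_pheno):
        pheno, true_f = balanced_pheno
        unbal = pheno.drop(index=pheno.index[::7]).reset_index(drop=True)
        res = fit_environment_blup(unbal)
        aligned = true_f.loc[list(res.line_ids)].to_numpy()
        assert np.corrcoef(res.blup, aligned)[0, 1] > 0.8
        assert res.components.sigma2_g >= 0

    def test_duplicate_keys_rejected(self):
        p = pd.DataFrame({"line_id": ["A", "A", "B"], "environment": "E1",
                          "replicate": "R1", "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="duplicate"):
            fit_environment_blup(p)

    def test_result_container(self, balanced_pheno):
        res = fit_environment_blup(balanced_pheno[0])
        assert isinstance(res, BlupResult)
        df = res.to_frame()
        assert set(df.columns) == {"line_id", "blup"}
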