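import numpy as np
import pandas as pd
import pytest
from scipy import stats

from husk_gs import (
    CVScheme,
    duncan_grouping,
    factorial_run,
    prediction_ability,
    run_cv,
    run_subgroup_cv,
)


@pytest.fixture(scope="module")
def cv_data(request):
    small_panel = request.getfixturevalue("small_panel")
    small_trait = request.getfixturevalue("small_trait")
    g, panel, _ = small_panel
    _, truth = small_trait
    return g, panel, truth.tbv


class TestPredictionAbility:
    def test_identity(self):
        x = np.arange(10.0)
        assert prediction_ability(x, x) == pytest.approx(1.0)

    def test_shuffled_null(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=500)
        rs = [prediction_ability(rng.permutation(y), y) for _ in range(30)]
        assert abs(np.mean(rs)) < 0.05

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(2, 40))
        assert prediction_ability(3.0 * a - 7.0, b) == pytest.approx(
            prediction_ability(a, b))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            prediction_ability([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            prediction_ability([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRunCV:
    def test_scheme_validation(self):
        with pytest.raises(ValueError):
            CVScheme(test_fraction=0.0)
        with pytest.raises(ValueError):
            CVScheme(scope="within_subgroup")
        with pytest.raises(ValueError):
            CVScheme(scope="whole_panel", focal_subgroup="SS")

    def test_deterministic_given_seed(self, cv_data):
        g, _, y = cv_data
        s = CVScheme(test_fraction=0.3, n_repeats=5, seed=3)
        a = run_cv(g, y, "rrblup", s)
        b = run_cv(g, y, "rrblup", s)
        np.testing.assert_array_equal(a.abilities, b.abilities)

    def test_ability_invariant_to_line_ordering(self, cv_data):
        g, _, y = cv_data
        s = CVScheme(test_fraction=0.3, n_repeats=5, seed=3)
        base = run_cv(g, y, "rrblup", s).mean_ability
        perm = np.random.default_rng(0).permutation(g.n_lines)
        g2 = g.subset(line_idx=perm)
        shuf = run_cv(g2, np.asarray(y)[perm], "rrblup", s).mean_ability
        # same distribution over splits; means agree closely over repeats
        assert abs(base - shuf) < 0.15

    def test_signal_detected(self, cv_data):
        g, _, y = cv_data
        res = run_cv(g, y, "rrblup", CVScheme(0.3, 10, seed=5))
        assert res.mean_ability > 0.3

    def test_tiny_test_set_rejected(self, cv_data):
        g, _, y = cv_data
        with pytest.raises(ValueError, match="test set"):
            run_cv(g, y, "rrblup", CVScheme(0.01, 2, seed=1))


class TestSubgroupCV:
    def test_within_partition_contract(self, cv_data):
        g, panel, y = cv_data
        sub = panel.set_index("line_id").loc[list(g.line_ids), "subgroup"].to_numpy()
        focal_n = int((sub == "TST").sum())
        s = CVScheme(0.3, 3, "within_subgroup", "TST", seed=2)
        res = run_subgroup_cv(g, y, panel, "rrblup", s)
        assert len(res.abilities) == 3

    def test_across_test_size(self, cv_data):
        g, panel, y = cv_data
        sub = panel.set_index("line_id").loc[list(g.line_ids), "subgroup"].to_numpy()
        n_focal = int((sub == "TST").sum())
        n_other = len(sub) - n_focal
        n_test_focal = int(np.floor(0.3 * n_focal + 0.5))
        # across-subgroup: test = focal remainder + all other lines
        expected_test = n_test_focal + n_other
        expected_train = n_focal - n_test_focal
        assert expected_train + expected_test == len(sub)

    def test_small_focal_subgroup_rejected(self, cv_data):
        g, panel, y = cv_data
        panel2 = panel.copy()
        panel2.loc[panel2.index[:-5], "subgroup"] = "NSS"
        panel2.loc[panel2.index[-5:], "subgroup"] = "SS"
        with pytest.raises(ValueError, match="fewer than 10"):
            run_subgroup_cv(g, y, panel2, "rrblup",
                            CVScheme(0.3, 2, "within_subgroup", "SS", seed=1))

    def test_divergent_subgroup_predicts_better_within_than_across(self):
        # trait whose marker effects in the focal subgroup are unrelated to
        # the effects in the rest of the panel: training inside the
        # subgroup should transfer poorly to outside lines
        from husk_gs import SimulationConfig, simulate_structured_genotypes

        cfg = SimulationConfig(n_markers=600, seed=51)
        g, panel, _ = simulate_structured_genotypes(cfg)
        rng = np.random.default_rng(5)
        m = g.n_markers
        eff_other = rng.normal(0, 1 / np.sqrt(m), m)
        eff_tst = rng.normal(0, 1 / np.sqrt(m), m)
        tst = (panel.set_index("line_id").loc[list(g.line_ids), "subgroup"]
               == "TST").to_numpy()
        tbv = np.where(tst, g.dosages @ eff_tst, g.dosages @ eff_other)
        y = tbv + rng.normal(0, tbv.std() * 0.8, len(tbv))
        w = run_subgroup_cv(g, y, panel, "rrblup",
                            CVScheme(0.3, 30, "within_subgroup", "TST", seed=8))
        a = run_subgroup_cv(g, y, panel, "rrblup",
                            CVScheme(0.3, 30, "across_subgroup", "TST", seed=8))
        assert w.mean_ability > a.mean_ability


class TestFactorialRun:
    def test_cross_product_row_count(self, cv_data):
        g, panel, y = cv_data
        schemes = [CVScheme(0.3, 2, seed=1)]
        tbl = factorial_run({"sim": g}, y, ["rrblup"], schemes,
                            densities=[0.5, 1.0], panel=panel)
        # 1 platform x 2 densities x 1 model x 1 scheme x 2 repeats
        assert len(tbl) == 4
        assert set(tbl["density_r2"]) == {0.5, 1.0}

    def test_rerun_identical(self, cv_data):
        g, panel, y = cv_data
        schemes = [CVScheme(0.25, 2, seed=9)]
        t1 = factorial_run({"sim": g}, y, ["rrblup"], schemes, panel=panel)
        t2 = factorial_run({"sim": g}, y, ["rrblup"], schemes, panel=panel)
        pd.testing.assert_frame_equal(t1, t2)

    def test_failed_cell_recorded_not_fatal(self, cv_data):
        g, panel, y = cv_data
        schemes = [CVScheme(0.3, 2, "within_subgroup", "SS", seed=1)]
        panel2 = panel.copy()
        panel2["subgroup"] = "NSS"  # SS empty -> cell fails
        tbl = factorial_run({"sim": g}, y, ["rrblup"], schemes, panel=panel2)
        assert len(tbl) == 2
        assert tbl["ability"].isna().all()


class TestDuncanGrouping:
    def test_forced_separation(self):
        rng = np.random.default_rng(1)
        comp = duncan_grouping({"lo": rng.normal(0, 1, 100),
                                "hi": rng.normal(5, 1, 100)})
        assert comp.letters["hi"] == "a"
        assert comp.letters["lo"] == "b"

    def test_pair_agrees_with_pooled_t_test(self):
        rng = np.random.default_rng(7)
        for shift in (0.0, 0.1, 0.3, 1.0):
            a = rng.normal(0, 1, 60)
            b = rng.normal(shift, 1, 60)
            comp = duncan_grouping({"a": a, "b": b}, alpha=0.05)
            separated = comp.letters["a"] != comp.letters["b"]
            t_sig = stats.ttest_ind(a, b).pvalue < 0.05
            assert separated == t_sig

    def test_letters_respect_significance_invariant(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(mu, 1, 50)
                  for i, mu in enumerate([0.0, 0.2, 1.5, 3.0])}
        comp = duncan_grouping(groups)
        # groups sharing a letter must not be the extreme pair
        assert not (set(comp.letters["g0"]) & set(comp.letters["g3"]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            duncan_grouping({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            duncan_grouping({"a": [1.0, 1.0], "b": [1.0, 1.0]})
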