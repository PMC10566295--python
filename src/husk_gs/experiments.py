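"""End-to-end reproducibility experiments.

Each function runs a complete pipeline on synthetic panels emulating the
study design (438 lines in four subgroups, 3 environments x 2 replicates,
trait heritability 0.41) and returns the measured quantity.  Problem sizes
are scaled to desk-scale marker counts; the panel-defining parameters
(subgroup sizes, heritability, replicate structure) are the emulated
design.  The acceptance script and the acceptance tests both drive these
functions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .evaluation import CVScheme, duncan_grouping, run_cv, run_subgroup_cv
from .genotype import GenotypeMatrix
from .ld import density_sweep
from .models import RRBLUP, BayesianAlphabetRegressor
from .simulate import (
    SimulationConfig,
    hudson_fst,
    simulate_structured_genotypes,
    simulate_trait,
)
from .traits import (
    HuskMeasurement,
    MoistureSeries,
    VarianceComponents,
    compute_auddc,
    compute_hti,
    estimate_heritability,
    fit_environment_blup,
)

TRAIT_DAYS = (34, 40, 46, 52, 58)


def _cfg(seed: int, **kw) -> SimulationConfig:
    return SimulationConfig(seed=seed, **kw)


def _blup_values(g, pheno):
    res = fit_environment_blup(pheno)
    order = {l: i for i, l in enumerate(res.line_ids)}
    return np.asarray([res.blup[order[l]] for l in g.line_ids]), res


# ------------------------------------------------------------ trait formulas
def auddc_worked_values() -> dict:
    """Trapezoid area for the study's measurement days and a tiny series."""
    const = compute_auddc(MoistureSeries("L", TRAIT_DAYS, [1.0] * 5))
    small = compute_auddc(MoistureSeries("L", [0, 1, 2], [2.0, 4.0, 6.0]))
    return {"constant_reading_area": const, "small_series_area": small}


def hti_worked_values() -> dict:
    return {
        "loose10_tight8_pct": compute_hti(HuskMeasurement("L", 10.0, 8.0)),
        "equal_perimeters_pct": compute_hti(HuskMeasurement("L", 12.0, 12.0)),
    }


def heritability_plugin_value() -> float:
    v = VarianceComponents(2.0, 3.0, 6.0, n_env=3, n_rep=2, mu=0.0)
    return estimate_heritability(v)


# ------------------------------------------------------------- heritability
def heritability_recovery(seed: int, n_panels: int = 30,
                          n_markers: int = 800) -> float:
    """Mean estimated broad-sense h2 over full simulate->REML pipelines."""
    h2s = []
    for k in range(n_panels):
        cfg = _cfg(seed + 1000 + k, n_markers=n_markers)
        g, panel, t0 = simulate_structured_genotypes(cfg)
        pheno, _ = simulate_trait(g, panel, cfg, "polygenic", t0)
        res = fit_environment_blup(pheno)
        h2s.append(estimate_heritability(res.components))
    return float(np.mean(h2s))


def realized_fst(seed: int, target: float = 0.3, n_seeds: int = 20) -> float:
    """Mean Hudson Fst between two pure subgroups at a known divergence."""
    vals = []
    for k in range(n_seeds):
        cfg = SimulationConfig(
            subgroup_sizes={"NSS": 50, "SS": 50, "TST": 50, "MIXED": 1},
            n_markers=200, fst=target, seed=seed + 70 + k)
        _, _, truth = simulate_structured_genotypes(cfg)
        vals.append(hudson_fst(truth.subgroup_freqs["NSS"],
                               truth.subgroup_freqs["TST"]))
    return float(np.mean(vals))


# ------------------------------------------------------- model equivalences
def rrblup_gblup_agreement(seed: int, n: int = 300, m: int = 1000) -> float:
    """GEBV correlation of marker-based rrBLUP against a kinship-based
    gBLUP oracle that solves the mixed-model equations directly with its
    own REML grid search."""
    rng = np.random.default_rng(seed + 11)
    X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
    eff = rng.normal(0, 1 / np.sqrt(m), m)
    tbv = X @ eff
    y = tbv + rng.normal(0, tbv.std(), n)

    rr = RRBLUP().fit(X, y)

    # independent oracle: REML on the genomic relationship matrix
    Zc = X - X.mean(axis=0)
    K = Zc @ Zc.T
    one = np.ones(n)

    def restricted_ll(lam):
        H = K + lam * np.eye(n)
        Hi = np.linalg.inv(H)
        a = one @ Hi @ one
        P = Hi - (Hi @ np.outer(one, one) @ Hi) / a
        _, ld = np.linalg.slogdet(H)
        return -0.5 * ((n - 1) * np.log(y @ P @ y) + ld + np.log(a))

    grid = np.exp(np.linspace(-10, 10, 120))
    lls = [restricted_ll(l) for l in grid]
    lam = grid[int(np.argmax(lls))]
    for _ in range(3):  # local refinement
        lo, hi = lam / 3, lam * 3
        grid = np.exp(np.linspace(np.log(lo), np.log(hi), 60))
        lls = [restricted_ll(l) for l in grid]
        lam = grid[int(np.argmax(lls))]
    H = K + lam * np.eye(n)
    Hi = np.linalg.inv(H)
    mu = (one @ Hi @ y) / (one @ Hi @ one)
    u_gblup = K @ Hi @ (y - mu)
    u_rr = rr.predict(X) - rr.intercept_
    return float(np.corrcoef(u_rr, u_gblup)[0, 1])


def ridge_closed_form_error(seed: int, n_instances: int = 5) -> float:
    """Max deviation of fixed-lambda rrBLUP effects from the primal ridge
    solution over random 50 x 20 instances."""
    rng = np.random.default_rng(seed + 13)
    worst = 0.0
    for _ in range(n_instances):
        X = rng.normal(size=(50, 20))
        y = rng.normal(size=50)
        lam = float(rng.uniform(0.2, 5.0))
        mdl = RRBLUP(lambda_=lam).fit(X, y)
        Zc = X - X.mean(axis=0)
        ref = np.linalg.solve(Zc.T @ Zc + lam * np.eye(20),
                              Zc.T @ (y - mdl.intercept_))
        worst = max(worst, float(np.abs(mdl.coef_ - ref).max()))
    return worst


def bayes_ridge_agreement(seed: int, n: int = 200, m: int = 500,
                          iters: int = 3000) -> dict:
    """BRR vs rrBLUP GEBV correlation on a polygenic trait, and the
    prior-collapse check BayesC(pi=0) vs BRR."""
    rng = np.random.default_rng(seed + 17)
    X = rng.binomial(2, rng.uniform(0.1, 0.9, m), size=(n, m)).astype(float)
    eff = rng.normal(0, 1 / np.sqrt(m), m)
    tbv = X @ eff
    y = tbv + rng.normal(0, tbv.std(), n)
    rr = RRBLUP().fit(X, y)
    brr = BayesianAlphabetRegressor("BRR", n_iter=iters, burnin=iters // 3,
                                    random_state=seed + 18).fit(X, y)
    bc0 = BayesianAlphabetRegressor("BayesC", n_iter=iters, burnin=iters // 3,
                                    random_state=seed + 18, pi=0.0,
                                    estimate_pi=False).fit(X, y)
    p_rr, p_brr, p_bc0 = rr.predict(X), brr.predict(X), bc0.predict(X)
    return {
        "brr_vs_rrblup": float(np.corrcoef(p_brr, p_rr)[0, 1]),
        "bayesc_pi0_vs_brr": float(np.corrcoef(p_bc0, p_brr)[0, 1]),
    }


# ------------------------------------------------------------ CV experiments
def null_trait_ability(seed: int, n_repeats: int = 50,
                       n_markers: int = 800) -> float:
    """Mean rrBLUP prediction ability for heritability-zero traits.

    Each repeat draws a fresh noise trait on the same panel: a single
    finite panel has a persistent accidental alignment between kinship and
    any one noise vector, so the calibration averages over traits.
    """
    cfg = _cfg(seed + 31, n_markers=n_markers, h2_target=0.0)
    g, panel, t0 = simulate_structured_genotypes(cfg)
    vals = []
    for rep in range(n_repeats):
        cfg_r = _cfg(seed + 4000 + rep, n_markers=n_markers, h2_target=0.0)
        pheno, _ = simulate_trait(g, panel, cfg_r, "polygenic", t0)
        ym = (pheno.groupby("line_id")["value"].mean()
              .loc[list(g.line_ids)].to_numpy())
        r = run_cv(g, ym, "rrblup", CVScheme(0.2, 1, seed=seed + rep),
                   cell_tag="null")
        vals.append(r.abilities[0])
    return float(np.mean(vals))


def training_fraction_trend(seed: int, n_markers: int = 1500,
                            n_repeats: int = 50) -> dict:
    """Mean rrBLUP ability for each test fraction 0.1 ... 0.9."""
    cfg = _cfg(seed + 21, n_markers=n_markers)
    g, panel, t0 = simulate_structured_genotypes(cfg)
    pheno, _ = simulate_trait(g, panel, cfg, "polygenic", t0)
    yb, _ = _blup_values(g, pheno)
    fracs = [round(0.1 * k, 1) for k in range(1, 10)]
    means = {}
    for tf in fracs:
        res = run_cv(g, yb, "rrblup", CVScheme(tf, n_repeats, seed=seed + 5),
                     cell_tag=f"tf{tf}")
        means[tf] = res.mean_ability
    rho = float(stats.spearmanr(fracs, [means[f] for f in fracs]).statistic)
    return {"means": means, "spearman": rho}


def density_experiment(seed: int, n_repeats: int = 50) -> dict:
    """Prediction ability after LD pruning at the grid's extreme analogs.

    The panel emulates a dense genotyping array: short haplotype blocks of
    near-duplicate markers (block length 4, adjacent r2 0.95), so pruning
    at r2 > 0.1 removes most markers while keeping one tag per block.
    """
    cfg = SimulationConfig(n_markers=2400, block_len=4, within_block_r2=0.95,
                           seed=seed + 11)
    g, panel, t0 = simulate_structured_genotypes(cfg)
    pheno, _ = simulate_trait(g, panel, cfg, "polygenic", t0)
    yb, _ = _blup_values(g, pheno)
    sweep = density_sweep(g, [0.01, 0.1, 1.0])
    abilities = {}
    order = {mid: i for i, mid in enumerate(g.marker_ids)}
    for thr, kept in sweep.items():
        idx = np.asarray([order[k] for k in kept])
        gm = g.subset(marker_idx=idx)
        res = run_cv(gm, yb, "rrblup",
                     CVScheme(0.3, n_repeats, seed=seed + 4),
                     cell_tag=f"dens{thr}")
        abilities[thr] = res.abilities
    p_decline = float(stats.ttest_ind(abilities[0.01], abilities[0.1],
                                      equal_var=False,
                                      alternative="less").pvalue)
    p_parity = float(stats.ttest_ind(abilities[0.1], abilities[1.0],
                                     equal_var=False).pvalue)
    return {
        "kept": {t: len(v) for t, v in sweep.items()},
        "mean_ability": {t: float(np.mean(a)) for t, a in abilities.items()},
        "p_heavy_pruning_lower": p_decline,
        "p_moderate_vs_full": p_parity,
    }


def architecture_comparison(seed: int, n_repeats: int = 30) -> dict:
    """Model ranking by trait architecture.

    Oligogenic (5 QTL, h2 0.5): variable-selection priors should match or
    beat the common-variance ridge.  Polygenic: all six models should be
    close to each other.
    """
    # oligogenic trait on a single-observation design
    cfg_o = SimulationConfig(
        subgroup_sizes={"NSS": 100, "SS": 30, "TST": 100, "MIXED": 70},
        n_markers=400, n_qtl=5, h2_target=0.5, gxe_var_frac=0.0,
        n_env=1, n_rep=1, seed=seed + 41)
    g, panel, t0 = simulate_structured_genotypes(cfg_o)
    pheno, _ = simulate_trait(g, panel, cfg_o, "oligogenic", t0)
    ym = (pheno.groupby("line_id")["value"].mean()
          .loc[list(g.line_ids)].to_numpy())
    bp = dict(n_iter=1500, burnin=500, thin=2)
    sch = CVScheme(0.2, n_repeats, seed=seed + 7)
    olig = {
        "bayesB": run_cv(g, ym, "bayesB", sch, model_params=bp,
                         cell_tag="olig").mean_ability,
        "rrblup": run_cv(g, ym, "rrblup", sch, cell_tag="olig").mean_ability,
    }

    # fully polygenic trait (every marker causal), all six models
    cfg_p = SimulationConfig(
        subgroup_sizes={"NSS": 85, "SS": 25, "TST": 125, "MIXED": 65},
        n_markers=300, n_qtl=300, seed=seed + 61)
    g2, panel2, t2 = simulate_structured_genotypes(cfg_p)
    pheno2, _ = simulate_trait(g2, panel2, cfg_p, "polygenic", t2)
    yb2, _ = _blup_values(g2, pheno2)
    bp2 = dict(n_iter=1000, burnin=300, thin=2)
    sch2 = CVScheme(0.2, n_repeats, seed=seed + 12)
    poly = {"rrblup": run_cv(g2, yb2, "rrblup", sch2,
                             cell_tag="poly").mean_ability}
    for mdl in ("bayesA", "bayesB", "bayesC", "bl", "brr"):
        poly[mdl] = run_cv(g2, yb2, mdl, sch2, model_params=bp2,
                           cell_tag="poly").mean_ability
    return {"oligogenic": olig, "polygenic": poly}


def subgroup_scheme_comparison(seed: int, n_repeats: int = 30) -> dict:
    """Within- vs across-subgroup ability for a divergent focal subgroup."""
    cfg = _cfg(seed + 51, n_markers=600)
    g, panel, _ = simulate_structured_genotypes(cfg)
    rng = np.random.default_rng(seed + 5)
    m = g.n_markers
    eff_other = rng.normal(0, 1 / np.sqrt(m), m)
    eff_tst = rng.normal(0, 1 / np.sqrt(m), m)
    tst = (panel.set_index("line_id").loc[list(g.line_ids), "subgroup"]
           == "TST").to_numpy()
    tbv = np.where(tst, g.dosages @ eff_tst, g.dosages @ eff_other)
    y = tbv + rng.normal(0, tbv.std() * 0.8, len(tbv))
    w = run_subgroup_cv(g, y, panel, "rrblup",
                        CVScheme(0.3, n_repeats, "within_subgroup", "TST",
                                 seed=seed + 8))
    a = run_subgroup_cv(g, y, panel, "rrblup",
                        CVScheme(0.3, n_repeats, "across_subgroup", "TST",
                                 seed=seed + 8))
    return {"within": w.mean_ability, "across": a.mean_ability}


# --------------------------------------------------------------- grouping
def duncan_null_rate(seed: int, n_seeds: int = 40, k: int = 5,
                     n_obs: int = 100) -> float:
    """Fraction of null draws (all groups one distribution) in which every
    group shares the top letter."""
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(seed + 900 + s)
        groups = {f"g{i}": rng.normal(0, 1, n_obs) for i in range(k)}
        comp = duncan_grouping(groups, alpha=0.05)
        hits += int(all("a" in v for v in comp.letters.values()))
    return hits / n_seeds


def duncan_separation() -> dict:
    rng = np.random.default_rng(1)
    comp = duncan_grouping({"lo": rng.normal(0, 1, 100),
                            "hi": rng.normal(5, 1, 100)})
    return dict(comp.letters)
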