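"""Cross-validation engine for the factorial genomic-selection evaluation.

Repeated random splits (Monte-Carlo cross-validation): each repeat draws a
uniform test set of the requested fraction, fits the model on the
complement and scores the test set; prediction ability is the Pearson
correlation between predicted GEBVs and the observed values (multi-
environment BLUPs on real data, true breeding values in simulations).
Subgroup schemes sample the training set from one subgroup and test either
the subgroup's remainder (within) or the remainder plus all other
subgroups' lines (across).  Group differences are summarized with Duncan's
multiple range test letters.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype import GenotypeMatrix
from .models import BAYES_MODELS, BayesianAlphabetRegressor, RRBLUP

__all__ = [
    "CVScheme",
    "CVResult",
    "GroupComparison",
    "prediction_ability",
    "run_cv",
    "run_subgroup_cv",
    "factorial_run",
    "duncan_grouping",
    "make_model",
]

TRAIN_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 10))


@dataclass
class CVScheme:
    """One cross-validation design cell."""

    test_fraction: float = 0.2
    n_repeats: int = 100
    scope: str = "whole_panel"
    focal_subgroup: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.scope not in ("whole_panel", "within_subgroup", "across_subgroup"):
            raise ValueError(f"unknown scope {self.scope!r}")
        if self.scope == "whole_panel" and self.focal_subgroup is not None:
            raise ValueError("whole_panel scheme forbids a focal subgroup")
        if self.scope != "whole_panel" and self.focal_subgroup is None:
            raise ValueError("subgroup scheme requires a focal subgroup")


@dataclass
class CVResult:
    """Per-repeat prediction abilities for one evaluation cell."""

    scheme: CVScheme
    model: str
    abilities: np.ndarray
    density: float | None = None
    platform_tag: str | None = None

    def __post_init__(self) -> None:
        self.abilities = np.asarray(self.abilities, dtype=float)
        ok = self.abilities[~np.isnan(self.abilities)]
        if ok.size and (ok.min() < -1 - 1e-12 or ok.max() > 1 + 1e-12):
            raise ValueError("abilities must lie in [-1, 1]")

    @property
    def mean_ability(self) -> float:
        return float(np.nanmean(self.abilities))

    @property
    def sd_ability(self) -> float:
        return float(np.nanstd(self.abilities, ddof=1))


@dataclass
class GroupComparison:
    """Group means with Duncan multiple-range significance letters."""

    labels: list
    means: np.ndarray
    letters: dict = field(default_factory=dict)
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"group": self.labels, "mean": self.means,
                             "letters": [self.letters[g] for g in self.labels]})


def prediction_ability(gebv, observed) -> float:
    """Pearson correlation between predicted and observed values."""
    gebv = np.asarray(gebv, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if len(gebv) != len(observed) or len(gebv) < 3:
        raise ValueError("need >= 3 paired values")
    if gebv.std() == 0 or observed.std() == 0:
        raise ValueError("constant vector")
    return float(np.corrcoef(gebv, observed)[0, 1])


def make_model(name: str, seed: int | None = None, **params):
    """Model factory by field name (rrblup / bayesA / ... / brr)."""
    key = name.lower()
    if key == "rrblup":
        return RRBLUP(**params)
    for m in BAYES_MODELS:
        if key == m.lower():
            return BayesianAlphabetRegressor(model=m, random_state=seed, **params)
    raise ValueError(f"unknown model {name!r}")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def _repeat_rng(seed: int, cell: str, repeat: int) -> np.random.Generator:
    """Deterministic per-repeat generator independent of execution order."""
    return np.random.default_rng([seed, zlib.crc32(cell.encode()), repeat])


def _score_repeat(X, y, train_idx, test_idx, model_name, seed, model_params):
    model = make_model(model_name, seed=seed, **model_params)
    model.fit(X[train_idx], y[train_idx])
    pred = model.predict(X[test_idx])
    return prediction_ability(pred, y[test_idx])


def run_cv(g: GenotypeMatrix, y, model: str, scheme: CVScheme,
           model_params: dict | None = None, cell_tag: str = "") -> CVResult:
    """Whole-panel Monte-Carlo cross-validation for one model."""
    if scheme.scope != "whole_panel":
        raise ValueError("run_cv handles whole_panel schemes; "
                         "use run_subgroup_cv for subgroup scopes")
    X = g.dosages
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_test = _round_half_away(scheme.test_fraction * n)
    if n_test < 3:
        raise ValueError("test set smaller than 3 lines")
    model_params = model_params or {}
    # the cell identity excludes the model so that different models are
    # compared on identical split sequences (paired comparison)
    cell = f"{cell_tag}|whole|{scheme.test_fraction}"
    abilities = np.empty(scheme.n_repeats)
    for rep in range(scheme.n_repeats):
        rng = _repeat_rng(scheme.seed, cell, rep)
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        sub_seed = int(rng.integers(2 ** 31))
        abilities[rep] = _score_repeat(X, y, train_idx, test_idx, model,
                                       sub_seed, model_params)
    return CVResult(scheme=scheme, model=model, abilities=abilities)


def run_subgroup_cv(g: GenotypeMatrix, y, panel: pd.DataFrame, model: str,
                    scheme: CVScheme, model_params: dict | None = None,
                    cell_tag: str = "") -> CVResult:
    """Subgroup-structured cross-validation.

    The training set is sampled from the focal subgroup at fraction
    ``1 - test_fraction``; the test set is the subgroup's remainder
    (``within_subgroup``) or the remainder plus every non-focal line
    (``across_subgroup``).
    """
    if scheme.scope == "whole_panel":
        raise ValueError("whole_panel scheme: use run_cv")
    sub = panel.set_index("line_id").loc[list(g.line_ids), "subgroup"].to_numpy()
    focal = np.flatnonzero(sub == scheme.focal_subgroup)
    others = np.flatnonzero(sub != scheme.focal_subgroup)
    if len(focal) < 10:
        raise ValueError("focal subgroup has fewer than 10 lines")
    n_test_focal = _round_half_away(scheme.test_fraction * len(focal))
    n_train = len(focal) - n_test_focal
    if n_test_focal < 3 and scheme.scope == "within_subgroup":
        raise ValueError("focal-subgroup test remainder smaller than 3")
    X = g.dosages
    y = np.asarray(y, dtype=float)
    model_params = model_params or {}
    cell = f"{cell_tag}|{scheme.scope}|{scheme.focal_subgroup}|{scheme.test_fraction}"
    abilities = np.empty(scheme.n_repeats)
    for rep in range(scheme.n_repeats):
        rng = _repeat_rng(scheme.seed, cell, rep)
        perm = rng.permutation(focal)
        train_idx = perm[:n_train]
        rest = perm[n_train:]
        test_idx = rest if scheme.scope == "within_subgroup" else np.concatenate([rest, others])
        sub_seed = int(rng.integers(2 ** 31))
        abilities[rep] = _score_repeat(X, y, train_idx, test_idx, model,
                                       sub_seed, model_params)
    return CVResult(scheme=scheme, model=model, abilities=abilities)


def factorial_run(g_sets: dict, y, models, schemes, densities=None,
                  panel: pd.DataFrame | None = None,
                  model_params: dict | None = None) -> pd.DataFrame:
    """Full cross-product of platform x model x density x scheme.

    ``g_sets`` maps a platform tag to a (pre-pruned) panel or, when
    ``densities`` is given, to a dict density -> panel.  Failed cells are
    recorded with NaN abilities rather than raised.  Returns a tidy frame
    with one row per repeat.
    """
    from .ld import PruneConfig, prune_by_ld

    rows = []
    for tag, gset in g_sets.items():
        by_density = (gset if isinstance(gset, dict) else
                      {d: None for d in (densities or [1.0])})
        for dens in by_density:
            gm = by_density[dens] if isinstance(gset, dict) else (
                gset if dens >= 1.0 else prune_by_ld(gset, PruneConfig(dens))[0])
            for model in models:
                for scheme in schemes:
                    cell_tag = f"{tag}|{dens}"
                    try:
                        if scheme.scope == "whole_panel":
                            res = run_cv(gm, y, model, scheme, model_params, cell_tag)
                        else:
                            res = run_subgroup_cv(gm, y, panel, model, scheme,
                                                  model_params, cell_tag)
                        abil = res.abilities
                    except ValueError:
                        abil = np.full(scheme.n_repeats, np.nan)
                    for rep, a in enumerate(abil):
                        rows.append({
                            "platform_tag": tag, "model": model,
                            "density_r2": dens, "scope": scheme.scope,
                            "focal_subgroup": scheme.focal_subgroup,
                            "test_fraction": scheme.test_fraction,
                            "repeat": rep, "ability": a})
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- Duncan
def duncan_grouping(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """Duncan's multiple range test with significance letters.

    ``groups`` maps a label to its observations.  Critical values are
    studentized-range quantiles at Duncan's protection levels
    ``1 - (1 - alpha)**(p - 1)`` for a span of ``p`` ordered means, with the
    pooled error variance of the one-way ANOVA; unequal group sizes use the
    harmonic-mean size.  Labels sharing no letter differ significantly.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    obs = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(len(v) < 2 for v in obs.values()):
        raise ValueError("every group needs at least 2 observations")
    k = len(labels)
    sizes = np.asarray([len(obs[l]) for l in labels], dtype=float)
    means = np.asarray([obs[l].mean() for l in labels])
    n_total = int(sizes.sum())
    df_err = n_total - k
    mse = sum(((obs[l] - obs[l].mean()) ** 2).sum() for l in labels) / df_err
    if mse <= 0:
        raise ValueError("zero pooled error variance")
    nh = k / (1.0 / sizes).sum()
    se = np.sqrt(mse / nh)

    order = np.argsort(-means)  # descending
    sorted_means = means[order]
    crit = {p: stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_err) * se
            for p in range(2, k + 1)}

    # protected step-down range testing: a range wholly inside a
    # non-significant wider range is declared non-significant untested
    ns = np.zeros((k, k), dtype=bool)
    for i in range(k):
        ns[i, i] = True
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if ns[i, j]:
                continue
            if sorted_means[i] - sorted_means[j] <= crit[span]:
                ns[i:j + 1, i:j + 1] = True

    # maximal non-significant intervals -> letters
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and ns[i, j + 1]:
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    seen = set()
    maximal = [iv for iv in maximal if not (iv in seen or seen.add(iv))]

    letters_sorted = ["" for _ in range(k)]
    for letter_i, (a, b) in enumerate(maximal):
        ch = chr(ord("a") + letter_i)
        for t in range(a, b + 1):
            letters_sorted[t] += ch
    letters = {labels[order[t]]: letters_sorted[t] for t in range(k)}
    return GroupComparison(labels=labels, means=means, letters=letters, alpha=alpha)
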