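"""Trait-level statistics: husk-tightness index, area under the dry-down
curve, multi-environment BLUP with variance components, broad-sense
heritability, and Pearson correlation testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HuskMeasurement",
    "MoistureSeries",
    "VarianceComponents",
    "BlupResult",
    "compute_hti",
    "compute_auddc",
    "fit_environment_blup",
    "estimate_heritability",
    "correlation_test",
]


@dataclass
class HuskMeasurement:
    """One husk perimeter measurement pair (cm) for a line replicate."""

    line_id: str
    loose_perimeter: float
    tight_perimeter: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.loose_perimeter <= 0 or self.tight_perimeter <= 0:
            raise ValueError("perimeters must be positive")
        if self.tight_perimeter > self.loose_perimeter:
            raise ValueError("tight perimeter exceeds loose perimeter")


@dataclass
class MoistureSeries:
    """Converted kernel-moisture meter readings over days after pollination."""

    line_id: str
    days: np.ndarray
    readings: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.readings = np.asarray(self.readings, dtype=float)
        if len(self.days) != len(self.readings):
            raise ValueError("days and readings lengths differ")
        if len(self.days) < 2:
            raise ValueError("need at least 2 measurements")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.days)


@dataclass
class VarianceComponents:
    """REML variance components of the multi-environment trait model."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: int
    mu: float

    def __post_init__(self) -> None:
        if min(self.sigma2_g, self.sigma2_ge, self.sigma2_e) < 0:
            raise ValueError("variance components must be non-negative")
        if self.n_env < 1 or self.n_rep < 1:
            raise ValueError("need n_env >= 1 and n_rep >= 1")


@dataclass
class BlupResult:
    """Per-line BLUP values (overall mean + predicted line effect)."""

    line_ids: np.ndarray
    blup: np.ndarray
    components: VarianceComponents

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"line_id": self.line_ids, "blup": self.blup})


def compute_hti(m: HuskMeasurement) -> float:
    """Husk tightness index: (loose - tight) / loose x 100%.

    Larger values mean a looser husk.
    """
    return (m.loose_perimeter - m.tight_perimeter) / m.loose_perimeter * 100.0


def compute_auddc(s: MoistureSeries) -> float:
    """Area under the dry-down curve: trapezoidal sum of the readings over
    the measurement days, ``sum_i [(g_i + g_{i+1})/2] (t_{i+1} - t_i)``.
    """
    return float(np.trapezoid(s.readings, s.days))


def estimate_heritability(v: VarianceComponents) -> float:
    """Broad-sense heritability ``sg2 / (sg2 + sge2/e + se2/(r e))``."""
    denom = v.sigma2_g + v.sigma2_ge / v.n_env + v.sigma2_e / (v.n_rep * v.n_env)
    if denom <= 0:
        raise ValueError("all variance components are zero")
    return v.sigma2_g / denom


def correlation_test(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# --------------------------------------------------------------------- BLUP
def _is_balanced(p: pd.DataFrame) -> bool:
    counts = p.groupby(["line_id", "environment"], observed=True).size()
    if counts.empty or counts.nunique() != 1:
        return False
    envs_per_line = p.groupby("line_id", observed=True)["environment"].nunique()
    n_env = p["environment"].nunique()
    return bool((envs_per_line == n_env).all())


def _balanced_anova_reml(p: pd.DataFrame) -> tuple[VarianceComponents, pd.Series]:
    """Closed-form REML (= ANOVA expected-mean-squares) for the balanced
    lines x environments x replicates design with environment and
    replicate-within-environment fixed.
    """
    e = p["environment"].nunique()
    r = p.groupby(["line_id", "environment"], observed=True).size().iloc[0]
    gmeans = p.groupby("line_id", observed=True)["value"].mean()
    g = len(gmeans)
    grand = p["value"].mean()
    cell = p.groupby(["line_id", "environment"], observed=True)["value"].mean().unstack()
    env_mean = p.groupby("environment", observed=True)["value"].mean()

    ss_g = e * r * float(((gmeans - grand) ** 2).sum())
    inter = cell.sub(gmeans, axis=0).sub(env_mean, axis=1) + grand
    ss_ge = r * float((inter ** 2).sum().sum())
    # residual after line-x-env cell means and rep-within-env effects
    cell_long = p.merge(cell.stack().rename("cell").reset_index(),
                        on=["line_id", "environment"])
    rep_dev = (cell_long.groupby(["environment", "replicate"], observed=True)["value"].transform("mean")
               - cell_long.groupby("environment", observed=True)["value"].transform("mean"))
    resid = cell_long["value"] - cell_long["cell"] - rep_dev
    ss_err = float((resid ** 2).sum())

    df_g, df_ge, df_err = g - 1, (g - 1) * (e - 1), e * (g - 1) * (r - 1)
    ms_g = ss_g / df_g
    if df_err > 0:
        ms_err = ss_err / df_err
    else:
        ms_err = 0.0
    if e > 1:
        ms_ge = ss_ge / df_ge
        s2e = ms_err
        s2ge = max(0.0, (ms_ge - ms_err) / r)
        s2g = max(0.0, (ms_g - ms_ge) / (e * r))
    else:
        # single environment: no GxE component identifiable
        s2ge = 0.0
        if r > 1:
            s2e = ms_err
            s2g = max(0.0, (ms_g - ms_err) / r)
        else:
            # one observation per line: genetic and residual variance are
            # confounded; attribute all line-to-line variance to genetics
            s2e = 0.0
            s2g = ms_g / r
    v = VarianceComponents(sigma2_g=s2g, sigma2_ge=s2ge, sigma2_e=s2e,
                           n_env=int(e), n_rep=int(r), mu=float(grand))
    return v, gmeans


def fit_environment_blup(p: pd.DataFrame) -> BlupResult:
    """Fit the multi-environment mixed model and return per-line BLUPs.

    Model: ``y_ijk = mu + env_i + rep(env)_ij + f_k + (f x e)_ik + eps``
    with environment and replicate-within-environment fixed, line and
    line-x-environment random.  Balanced designs use the closed-form
    ANOVA/REML solution; unbalanced designs fall back to a numerical REML
    fit (statsmodels MixedLM).  Negative component estimates are truncated
    at zero.  The returned BLUP is the overall mean plus the shrunken line
    effect.
    """
    p = pd.DataFrame(p)
    required = {"line_id", "environment", "replicate", "value"}
    if not required.issubset(p.columns):
        raise ValueError(f"phenotype records need columns {sorted(required)}")
    if p.duplicated(["line_id", "environment", "replicate"]).any():
        raise ValueError("duplicate (line, environment, replicate) keys")
    if p["line_id"].nunique() < 2:
        raise ValueError("need at least 2 lines")
    n_env = p["environment"].nunique()
    if n_env < 2:
        warnings.warn("single environment: fitting without a GxE component")

    if p["value"].std() == 0:
        mu = float(p["value"].iloc[0])
        lines = np.asarray(sorted(p["line_id"].unique()), dtype=object)
        v = VarianceComponents(0.0, 0.0, 0.0, n_env,
                               int(p.groupby(["line_id", "environment"], observed=True).size().max()), mu)
        return BlupResult(lines, np.full(len(lines), mu), v)

    if _is_balanced(p):
        v, gmeans = _balanced_anova_reml(p)
        denom = v.sigma2_g + v.sigma2_ge / v.n_env + v.sigma2_e / (v.n_rep * v.n_env)
        shrink = v.sigma2_g / denom if denom > 0 else 0.0
        blup = v.mu + shrink * (gmeans.to_numpy() - v.mu)
        return BlupResult(np.asarray(gmeans.index, dtype=object), blup, v)

    return _mixedlm_blup(p)


def _mixedlm_blup(p: pd.DataFrame) -> BlupResult:
    import statsmodels.formula.api as smf

    p = p.copy()
    n_env = p["environment"].nunique()
    fixed = ("value ~ C(environment) + C(environment):C(replicate)"
             if n_env > 1 or p["replicate"].nunique() > 1 else "value ~ 1")
    vc = {"gxe": "0 + C(environment)"} if n_env > 1 else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(fixed, p, groups=p["line_id"],
                         re_formula="1", vc_formula=vc)
        fit = md.fit(reml=True, method="lbfgs")
    s2g = max(0.0, float(fit.cov_re.iloc[0, 0]))
    s2ge = max(0.0, float(fit.vcomp[0])) if vc else 0.0
    s2e = max(0.0, float(fit.scale))
    mu = float(p["value"].mean())
    reps = int(round(p.groupby(["line_id", "environment"], observed=True).size().mean()))
    v = VarianceComponents(s2g, s2ge, s2e, int(n_env), max(1, reps), mu)
    lines = sorted(p["line_id"].unique())
    re = fit.random_effects
    blup = np.asarray([mu + float(re[l].iloc[0]) for l in lines])
    return BlupResult(np.asarray(lines, dtype=object), blup, v)
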