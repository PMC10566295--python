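"""Structured maize-panel simulator.

Generates genotype panels with subgroup structure (Balding–Nichols
divergence from a shared ancestral population), block LD (first-order
Markov allele copying along markers within a block), inbred-line dosages,
multi-environment quantitative traits with a controlled broad-sense
heritability, and kernel-moisture dry-down series whose area statistic
correlates with a supplied trait at subgroup-specific target levels.

The default panel mirrors a temperate/tropical maize association panel:
438 lines in four subgroups (121 NSS, 30 SS, 186 TST, 101 MIXED),
phenotyped in 3 environments x 2 replicates, trait heritability 0.41.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, SUBGROUPS

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "simulate_structured_genotypes",
    "simulate_trait",
    "simulate_moisture_series",
    "hudson_fst",
]

#: default subgroup sizes of the emulated association panel
DEFAULT_SUBGROUP_SIZES = {"NSS": 121, "SS": 30, "TST": 186, "MIXED": 101}

#: default per-subgroup Balding–Nichols divergence from the ancestral pool;
#: temperate pools modest, tropical-subtropical the most diverged
DEFAULT_FST = {"NSS": 0.08, "SS": 0.12, "TST": 0.15}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic panel; defaults are the emulated study design."""

    subgroup_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUP_SIZES))
    n_markers: int = 2000
    n_chrom: int = 10
    fst: dict | float = field(default_factory=lambda: dict(DEFAULT_FST))
    block_len: int = 10
    within_block_r2: float = 0.5
    n_qtl: int = 200
    h2_target: float = 0.41
    n_env: int = 3
    n_rep: int = 2
    gxe_var_frac: float = 0.2
    inbreeding: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.subgroup_sizes.values()):
            raise ValueError("subgroup sizes must be positive")
        if not 0.0 <= self.h2_target <= 1.0:
            raise ValueError("h2_target must lie in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.block_len > self.n_markers:
            raise ValueError("block_len cannot exceed n_markers")
        if not 0.0 <= self.within_block_r2 <= 1.0:
            raise ValueError("within_block_r2 must lie in [0, 1]")
        fst = self.fst if isinstance(self.fst, dict) else {
            s: float(self.fst) for s in ("NSS", "SS", "TST")}
        for s, f in fst.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"fst[{s}] must lie in (0, 1)")
        self.fst = fst


@dataclass
class SimTruth:
    """Simulation ground truth recorded before noise is added."""

    qtl_ids: np.ndarray = None
    qtl_effects: np.ndarray = None  # full-length; exactly 0 off the QTL
    tbv: np.ndarray = None          # per line: sum_k dosage_ik * effect_k
    realized_h2: float = None
    ancestral_freqs: np.ndarray = None
    subgroup_freqs: dict = None     # subgroup -> per-marker frequency


# ------------------------------------------------------------------ genotypes
def _sample_haplotypes(freq: np.ndarray, block_id: np.ndarray, copy_prob: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Markov copying along markers: allele j equals allele j-1 with
    probability ``copy_prob`` (within a block) else a fresh Bernoulli draw.

    ``freq`` is (n_lines, n_markers); frequencies are constant within a
    block, so copying preserves the marginal frequency exactly and the
    expected squared correlation of adjacent markers is copy_prob**2.
    """
    n, m = freq.shape
    fresh = (rng.random((n, m)) < freq)
    if copy_prob <= 0.0:
        return fresh.astype(np.int8)
    copy = rng.random((n, m)) < copy_prob
    H = np.empty((n, m), dtype=np.int8)
    H[:, 0] = fresh[:, 0]
    for j in range(1, m):
        if block_id[j] != block_id[j - 1]:
            H[:, j] = fresh[:, j]
        else:
            H[:, j] = np.where(copy[:, j], H[:, j - 1], fresh[:, j])
    return H


def simulate_structured_genotypes(cfg: SimulationConfig):
    """Draw a structured genotype panel.

    Returns ``(GenotypeMatrix, panel, SimTruth)`` where ``panel`` is a
    DataFrame with columns line_id / subgroup and the truth object carries
    ancestral and per-subgroup allele frequencies (trait fields unset).

    Ancestral frequencies are Uniform(0.05, 0.95) per LD block; each pure
    subgroup's frequencies follow a Balding–Nichols Beta draw with its own
    divergence parameter; MIXED lines use a per-line Dirichlet convex
    mixture of the three pure subgroup frequency vectors.  Lines are
    inbreds: the second gamete copies the first with probability
    ``cfg.inbreeding``.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_markers

    # chromosome map: markers split evenly over chromosomes, blocks nested
    chrom_of = np.repeat(np.arange(cfg.n_chrom), math.ceil(m / cfg.n_chrom))[:m]
    pos = np.concatenate([np.arange(1, (chrom_of == c).sum() + 1) * 1000
                          for c in range(cfg.n_chrom)])
    block_id = np.empty(m, dtype=np.int64)
    b = 0
    for c in range(cfg.n_chrom):
        idx = np.flatnonzero(chrom_of == c)
        for s in range(0, len(idx), cfg.block_len):
            block_id[idx[s:s + cfg.block_len]] = b
            b += 1
    n_blocks = b

    # ancestral + Balding–Nichols subgroup frequencies, one draw per block
    p_anc_block = rng.uniform(0.05, 0.95, size=n_blocks)
    sub_freq_block = {}
    for s in ("NSS", "SS", "TST"):
        f = cfg.fst[s]
        a = p_anc_block * (1.0 - f) / f
        bpar = (1.0 - p_anc_block) * (1.0 - f) / f
        sub_freq_block[s] = np.clip(rng.beta(a, bpar), 1e-6, 1.0 - 1e-6)
    p_anc = p_anc_block[block_id]
    subgroup_freqs = {s: sub_freq_block[s][block_id] for s in ("NSS", "SS", "TST")}

    copy_prob = math.sqrt(cfg.within_block_r2)
    dosage_parts, line_ids, subgroups = [], [], []
    counter = 0
    for s in SUBGROUPS:
        n_s = cfg.subgroup_sizes.get(s, 0)
        if n_s == 0:
            continue
        if s == "MIXED":
            w = rng.dirichlet(np.ones(3), size=n_s)  # (n_s, 3)
            pure = np.stack([subgroup_freqs[t] for t in ("NSS", "SS", "TST")])
            freq = w @ pure.reshape(3, m)
        else:
            freq = np.broadcast_to(subgroup_freqs[s], (n_s, m)).copy()
        h1 = _sample_haplotypes(freq, block_id, copy_prob, rng)
        h2 = _sample_haplotypes(freq, block_id, copy_prob, rng)
        ibd = rng.random(n_s) < cfg.inbreeding
        h2 = np.where(ibd[:, None], h1, h2)
        dosage_parts.append((h1 + h2).astype(float))
        line_ids.extend(f"L{counter + i:04d}" for i in range(n_s))
        subgroups.extend([s] * n_s)
        counter += n_s

    marker_ids = np.asarray([f"M{j:05d}" for j in range(m)], dtype=object)
    g = GenotypeMatrix(
        line_ids=np.asarray(line_ids, dtype=object),
        marker_ids=marker_ids,
        dosages=np.vstack(dosage_parts),
        chrom=np.asarray([str(c + 1) for c in chrom_of], dtype=object),
        pos=pos,
        ref=np.repeat("A", m),
        alt=np.repeat("T", m),
    )
    panel = pd.DataFrame({"line_id": g.line_ids, "subgroup": subgroups})
    truth = SimTruth(ancestral_freqs=p_anc, subgroup_freqs=subgroup_freqs)
    return g, panel, truth


# ---------------------------------------------------------------------- trait
def simulate_trait(g: GenotypeMatrix, panel: pd.DataFrame, cfg: SimulationConfig,
                   architecture: str = "polygenic",
                   truth: SimTruth | None = None):
    """Simulate a multi-environment trait on an imputed panel.

    ``phenotype_ijk = mu + env_i + rep(env)_ij + tbv_k + ge_ik + eps_ijk``
    with the GxE and residual variances scaled so the expected broad-sense
    heritability ``sg2 / (sg2 + sge2/e + se2/(r e))`` equals
    ``cfg.h2_target``.  ``h2_target=0`` yields a pure-noise null trait: the
    drawn QTL effects and TBV are still recorded in the truth object but do
    not enter the phenotype.

    Returns ``(PhenotypeRecords DataFrame, SimTruth)``.
    """
    if g.missing_mask.any():
        raise ValueError("genotypes must be imputed before trait simulation")
    rng = np.random.default_rng([cfg.seed, 7])
    m = g.n_markers
    if architecture == "oligogenic":
        if cfg.n_qtl > 20:
            raise ValueError("oligogenic architecture requires n_qtl <= 20")
        n_qtl = cfg.n_qtl
        effect_scale = 1.0
    elif architecture == "polygenic":
        n_qtl = max(cfg.n_qtl, math.ceil(0.5 * m))
        effect_scale = 1.0 / math.sqrt(n_qtl)
    else:
        raise ValueError(f"unknown architecture {architecture!r}")

    qtl_idx = np.sort(rng.choice(m, size=n_qtl, replace=False))
    effects = np.zeros(m)
    effects[qtl_idx] = rng.normal(0.0, effect_scale, size=n_qtl)
    tbv = g.dosages @ effects
    sg2 = float(np.var(tbv))
    if sg2 == 0.0 and cfg.h2_target > 0.0 and n_qtl > 0:
        raise ValueError("zero genetic variance; cannot reach a positive h2 target")

    e, r = cfg.n_env, cfg.n_rep
    if cfg.h2_target > 0.0:
        sge2 = cfg.gxe_var_frac * sg2
        se2 = r * e * (sg2 / cfg.h2_target - sg2 - sge2 / e)
        if se2 < 0:
            raise ValueError("h2_target unattainable with this gxe_var_frac")
        genetic = tbv
    else:
        sge2 = 0.0
        se2 = sg2 if sg2 > 0 else 1.0
        genetic = np.zeros_like(tbv)

    mu = 30.0
    env_eff = rng.normal(0.0, 2.0, size=e)
    rep_eff = rng.normal(0.0, 0.5, size=(e, r))
    ge = rng.normal(0.0, math.sqrt(sge2), size=(g.n_lines, e)) if sge2 > 0 else np.zeros((g.n_lines, e))

    rows = []
    for i in range(e):
        for j in range(r):
            eps = rng.normal(0.0, math.sqrt(se2), size=g.n_lines)
            vals = mu + env_eff[i] + rep_eff[i, j] + genetic + ge[:, i] + eps
            rows.append(pd.DataFrame({
                "line_id": g.line_ids, "environment": f"E{i + 1}",
                "replicate": f"R{j + 1}", "value": vals}))
    pheno = pd.concat(rows, ignore_index=True)

    realized_h2 = sg2 / (sg2 + sge2 / e + se2 / (r * e)) if sg2 > 0 else 0.0
    out = SimTruth(
        qtl_ids=g.marker_ids[qtl_idx],
        qtl_effects=effects,
        tbv=tbv,
        realized_h2=realized_h2,
        ancestral_freqs=None if truth is None else truth.ancestral_freqs,
        subgroup_freqs=None if truth is None else truth.subgroup_freqs,
    )
    return pheno, out


# ------------------------------------------------------------------- moisture
def simulate_moisture_series(tbv_hti: np.ndarray, panel: pd.DataFrame,
                             target_corr: dict | float,
                             days=(34, 40, 46, 52, 58), seed: int = 0):
    """Kernel moisture dry-down curves whose trapezoidal area correlates
    with the supplied husk-tightness values at ``target_corr`` within each
    subgroup.

    Readings decline in expectation over days after pollination; a latent
    per-line wetness component (correlated with the supplied trait at the
    subgroup's target level) shifts the whole curve, so the area statistic
    inherits approximately the target correlation.

    Returns a list of :class:`~husk_gs.traits.MoistureSeries`.
    """
    from .traits import MoistureSeries

    days = np.asarray(days, dtype=float)
    if len(days) < 2:
        raise ValueError("need at least 2 measurement days")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing")
    tbv_hti = np.asarray(tbv_hti, dtype=float)
    rng = np.random.default_rng(seed)
    corr = (target_corr if isinstance(target_corr, dict)
            else {s: float(target_corr) for s in SUBGROUPS})
    for v in corr.values():
        if not -1.0 <= v <= 1.0:
            raise ValueError("target correlations must lie in [-1, 1]")

    latent = np.empty_like(tbv_hti)
    sub = panel["subgroup"].to_numpy()
    for s in np.unique(sub):
        idx = np.flatnonzero(sub == s)
        rho = corr.get(s, 0.0)
        x = tbv_hti[idx]
        z = (x - x.mean()) / x.std() if x.std() > 0 else np.zeros(len(idx))
        latent[idx] = rho * z + math.sqrt(max(0.0, 1 - rho ** 2)) * rng.normal(size=len(idx))

    out = []
    decline = 1.2  # % moisture per day, typical maize kernel dry-down
    for i, lid in enumerate(panel["line_id"]):
        readings = (55.0 + 2.5 * latent[i] - decline * (days - days[0])
                    + rng.normal(0.0, 0.3, size=len(days)))
        out.append(MoistureSeries(line_id=lid, days=days.copy(), readings=readings))
    return out


# ------------------------------------------------------------------------ Fst
def hudson_fst(p1: np.ndarray, p2: np.ndarray,
               n1: int | None = None, n2: int | None = None) -> float:
    """Hudson-type Fst between two populations (ratio-of-averages).

    With allele *frequencies* (``n1``/``n2`` omitted) the numerator is
    ``(p1-p2)**2``; with sample sizes given, the standard finite-sample
    correction ``p(1-p)/(n-1)`` is subtracted for each population.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    num = (p1 - p2) ** 2
    if n1 is not None:
        num = num - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return float(num[keep].mean() / den[keep].mean())
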