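"""Pairwise linkage-disequilibrium r² and sliding-window marker pruning.

r² is the squared Pearson correlation of dosage vectors (the composite LD
measure on genotypes); missing calls are excluded pairwise.  Pruning is the
indep-pairwise style sliding-window greedy reduction, run per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .genotype import GenotypeMatrix

__all__ = ["PruneConfig", "LDPruner", "pairwise_r2", "prune_by_ld", "density_sweep"]

DEFAULT_THRESHOLDS = (0.01, 0.1, 0.2, 0.5, 0.8, 1.0)


@dataclass
class PruneConfig:
    """Sliding-window pruning parameters.

    A pair is pruned only when its r² strictly exceeds the threshold, so
    ``r2_threshold = 1.0`` keeps every marker.
    """

    r2_threshold: float = 0.1
    window_size: int = 50
    step: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must lie in (0, 1]")
        if not self.window_size > self.step >= 1:
            raise ValueError("need window_size > step >= 1")


def _r2_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise r² of columns; NaN where a column is monomorphic on the
    pairwise-complete lines."""
    if np.isnan(X).any():
        m = X.shape[1]
        out = np.full((m, m), np.nan)
        for i in range(m):
            out[i, i] = 1.0 if np.nanstd(X[:, i]) > 0 else np.nan
            for j in range(i + 1, m):
                out[i, j] = out[j, i] = _pair_r2(X[:, i], X[:, j])
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = X.std(axis=0)
        c = np.corrcoef(X, rowvar=False)
    if np.ndim(c) == 0:
        c = np.asarray([[1.0]])
    c[sd == 0, :] = np.nan
    c[:, sd == 0] = np.nan
    return c ** 2


def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return np.nan
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def pairwise_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """r² between markers i and j over lines non-missing at both; NaN when
    either marker is monomorphic on the shared lines."""
    if i == j:
        x = g.dosages[:, i]
        x = x[~np.isnan(x)]
        return 1.0 if len(x) > 1 and x.std() > 0 else np.nan
    return _pair_r2(g.dosages[:, i], g.dosages[:, j])


class LDPruner(BaseEstimator, TransformerMixin):
    """Sliding-window greedy LD pruner (transformer over dosage columns).

    Within each window, while any kept pair has r² above the threshold, the
    member of an offending pair with the higher mean r² to the other kept
    window markers is removed (ties broken toward the later position).
    Windows advance by ``step`` markers along each chromosome.

    Attributes (after fit): ``support_`` boolean mask of kept markers in
    input order; ``kept_idx_`` integer indices.
    """

    def __init__(self, r2_threshold: float = 0.1, window_size: int = 50, step: int = 5):
        self.r2_threshold = r2_threshold
        self.window_size = window_size
        self.step = step

    def fit(self, X, y=None, chrom=None, pos=None):
        cfg = PruneConfig(self.r2_threshold, self.window_size, self.step)
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty genotype matrix")
        m = X.shape[1]
        keep = np.ones(m, dtype=bool)
        if cfg.r2_threshold < 1.0:
            chrom = np.zeros(m) if chrom is None else np.asarray(chrom)
            pos = np.arange(m) if pos is None else np.asarray(pos)
            for c in _unique_in_order(chrom):
                idx = np.flatnonzero(chrom == c)
                self._prune_chrom(X, idx, pos, keep, cfg)
        self.support_ = keep
        self.kept_idx_ = np.flatnonzero(keep)
        return self

    def _prune_chrom(self, X, idx, pos, keep, cfg):
        start = 0
        while True:
            win = idx[start:start + cfg.window_size]
            wk = win[keep[win]]
            if len(wk) > 1:
                r2 = _r2_matrix(X[:, wk])
                np.fill_diagonal(r2, np.nan)
                self._resolve(r2, wk, pos, keep, cfg.r2_threshold)
            if start + cfg.window_size >= len(idx):
                break
            start += cfg.step

    @staticmethod
    def _resolve(r2, wk, pos, keep, thr):
        alive = np.ones(len(wk), dtype=bool)
        while True:
            sub = r2[np.ix_(alive, alive)]
            with np.errstate(invalid="ignore"):
                offending = np.nansum(sub > thr, axis=1)
            if not offending.any():
                break
            mean_r2 = np.nanmean(np.where(np.isnan(sub), 0.0, sub), axis=1)
            cand = np.flatnonzero(offending > 0)
            local = np.flatnonzero(alive)
            # highest mean r2 to the rest of the window; ties -> later position
            key = [(mean_r2[c], pos[wk[local[c]]], wk[local[c]]) for c in cand]
            drop_local = local[cand[max(range(len(key)), key=lambda t: key[t])]]
            alive[drop_local] = False
            keep[wk[drop_local]] = False

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]


def _unique_in_order(a):
    """Unique values preserving first-appearance order."""
    seen, out = set(), []
    for v in a:
        if v not in seen:
            seen.add(v)
            out.append(v)
    return out


def prune_by_ld(g: GenotypeMatrix, cfg: PruneConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Prune a (chrom, pos)-sorted panel; returns the pruned panel and the
    kept marker ids in input order."""
    if g.n_markers == 0:
        raise ValueError("empty genotype matrix")
    pruner = LDPruner(cfg.r2_threshold, cfg.window_size, cfg.step)
    pruner.fit(g.dosages, chrom=g.chrom, pos=g.pos)
    return g.subset(marker_idx=pruner.kept_idx_), g.marker_ids[pruner.kept_idx_]


def density_sweep(g: GenotypeMatrix, thresholds=DEFAULT_THRESHOLDS,
                  window_size: int = 50, step: int = 5) -> dict:
    """Kept marker ids for each r² threshold of the density grid."""
    out = {}
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be positive")
        if t >= 1.0:
            out[t] = list(g.marker_ids)
        else:
            _, kept = prune_by_ld(g, PruneConfig(t, window_size, step))
            out[t] = list(kept)
    return out
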