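"""Genotype panel data model, readers/writers, marker QC and imputation.

Dosages are coded as the count of the alternate allele in {0, 1, 2}; missing
calls are carried as NaN in a float matrix.  Inbred-line panels are mostly
homozygous but heterozygous dosage 1 is allowed throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

SUBGROUPS = ("NSS", "SS", "TST", "MIXED")

__all__ = [
    "GenotypeMatrix",
    "MarkerQCReport",
    "MarkerQCFilter",
    "DosageImputer",
    "read_genotypes",
    "write_dosage_table",
    "filter_markers",
    "impute_missing",
    "allele_frequencies",
    "minor_allele_frequencies",
]


@dataclass
class GenotypeMatrix:
    """Lines x markers dosage matrix with per-marker map metadata.

    Parameters
    ----------
    line_ids : array of str
        Unique line identifiers (row order of ``dosages``).
    marker_ids : array of str
        Unique marker identifiers (column order of ``dosages``).
    dosages : ndarray of float, shape (n_lines, n_markers)
        Alt-allele counts in {0, 1, 2}; NaN marks missing calls.
    chrom, pos : per-marker chromosome label and 1-based physical position.
    ref, alt : per-marker reference / alternate allele symbols.
    """

    line_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = np.asarray(self.line_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        n, m = self.dosages.shape
        if len(self.line_ids) != n or len(self.marker_ids) != m:
            raise ValueError("dosages shape does not match id lengths")
        if len(set(self.line_ids)) != n:
            raise ValueError("duplicate line ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != m:
                raise ValueError(f"{name} length != n_markers")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.all(np.isin(np.round(vals, 9), (0.0, 1.0, 2.0))):
            bad = vals[~np.isin(np.round(vals, 9), (0.0, 1.0, 2.0))]
            # imputed matrices may hold fractional dosages; only reject
            # values outside the [0, 2] range
            if bad.min() < 0 or bad.max() > 2:
                raise ValueError("dosage values outside [0, 2]")

    # ------------------------------------------------------------------ basic
    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    def subset(self, line_idx=None, marker_idx=None) -> "GenotypeMatrix":
        """Row/column subset by integer index arrays (order preserved)."""
        li = np.arange(self.n_lines) if line_idx is None else np.asarray(line_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            line_ids=self.line_ids[li],
            marker_ids=self.marker_ids[mi],
            dosages=self.dosages[np.ix_(li, mi)],
            chrom=self.chrom[mi],
            pos=self.pos[mi],
            ref=self.ref[mi],
            alt=self.alt[mi],
        )

    def sort_markers(self) -> "GenotypeMatrix":
        """Return a copy with markers sorted by (chrom, pos), stable."""
        order = np.lexsort((self.pos, np.asarray(self.chrom, dtype=str)))
        return self.subset(marker_idx=order)


@dataclass
class MarkerQCReport:
    """Per-marker QC statistics and removal accounting.

    Removal reasons are disjoint: the MAF rule is checked first, except that
    fully-missing markers (undefined MAF) are always attributed to the
    missing-rate rule.
    """

    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_retained: int
    maf: np.ndarray = field(repr=False)
    missing_rate: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.n_input != self.n_removed_maf + self.n_removed_missing + self.n_retained:
            raise ValueError("QC accounting does not add up")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_maf": self.n_removed_maf,
            "n_removed_missing": self.n_removed_missing,
            "n_retained": self.n_retained,
        }


# --------------------------------------------------------------------- stats
def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Alt-allele frequency per marker from non-missing calls (NaN if none)."""
    dosages = np.asarray(dosages, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(dosages, axis=0) / 2.0


def minor_allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Minor-allele frequency in [0, 0.5]; invariant to allele relabeling."""
    p = allele_frequencies(dosages)
    return np.minimum(p, 1.0 - p)


# ----------------------------------------------------------------- estimators
class MarkerQCFilter(BaseEstimator, TransformerMixin):
    """Column filter retaining markers with MAF >= maf_min and
    missing rate <= miss_max (both thresholds inclusive).

    Attributes (after fit): ``maf_``, ``missing_rate_``, ``support_`` (bool
    mask of retained markers), ``removed_maf_``, ``removed_missing_``.
    """

    def __init__(self, maf_min: float = 0.05, miss_max: float = 0.2):
        self.maf_min = maf_min
        self.miss_max = miss_max

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty genotype matrix")
        self.maf_ = minor_allele_frequencies(X)
        self.missing_rate_ = np.isnan(X).mean(axis=0)
        all_missing = np.isnan(self.maf_)
        # first-failing-rule attribution: MAF first, but an all-missing
        # marker has no defined MAF and is attributed to the missing rule
        fail_maf = np.where(all_missing, False, self.maf_ < self.maf_min)
        fail_miss = ~fail_maf & (self.missing_rate_ > self.miss_max)
        self.removed_maf_ = fail_maf
        self.removed_missing_ = fail_miss
        self.support_ = ~(fail_maf | fail_miss)
        if not self.support_.any():
            raise ValueError("all markers removed by QC filter")
        return self

    def transform(self, X):
        check_is_fitted(self, "support_")
        return np.asarray(X, dtype=float)[:, self.support_]

    def report(self) -> MarkerQCReport:
        check_is_fitted(self, "support_")
        return MarkerQCReport(
            n_input=len(self.support_),
            n_removed_maf=int(self.removed_maf_.sum()),
            n_removed_missing=int(self.removed_missing_.sum()),
            n_retained=int(self.support_.sum()),
            maf=self.maf_,
            missing_rate=self.missing_rate_,
        )


class DosageImputer(BaseEstimator, TransformerMixin):
    """Fill missing dosages per marker with the training mean or mode.

    ``strategy='marker_mean'`` may yield fractional dosages in [0, 2];
    ``'marker_mode'`` keeps dosages integral (ties broken toward the
    smaller dosage).
    """

    def __init__(self, strategy: str = "marker_mean"):
        self.strategy = strategy

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.strategy not in ("marker_mean", "marker_mode"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if np.isnan(X).all(axis=0).any():
            raise ValueError(
                "fully-missing marker: run the QC filter before imputing")
        if self.strategy == "marker_mean":
            self.statistics_ = np.nanmean(X, axis=0)
        else:
            stats = np.empty(X.shape[1])
            for j in range(X.shape[1]):
                col = X[:, j]
                col = col[~np.isnan(col)]
                vals, counts = np.unique(col, return_counts=True)
                stats[j] = vals[np.argmax(counts)]  # first max -> smaller dosage
            self.statistics_ = stats
        return self

    def transform(self, X):
        check_is_fitted(self, "statistics_")
        X = np.asarray(X, dtype=float).copy()
        miss = np.isnan(X)
        X[miss] = np.broadcast_to(self.statistics_, X.shape)[miss]
        return X


# ------------------------------------------------------------------- wrappers
def filter_markers(g: GenotypeMatrix, maf_min: float = 0.05,
                   miss_max: float = 0.2) -> tuple[GenotypeMatrix, MarkerQCReport]:
    """Apply the MAF / missing-rate adoption criteria (inclusive thresholds)."""
    f = MarkerQCFilter(maf_min=maf_min, miss_max=miss_max).fit(g.dosages)
    kept = np.flatnonzero(f.support_)
    return g.subset(marker_idx=kept), f.report()


def impute_missing(g: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Replace missing dosages; non-missing cells are unchanged."""
    if not g.missing_mask.any():
        return g
    imp = DosageImputer(strategy=method).fit(g.dosages)
    out = GenotypeMatrix(g.line_ids, g.marker_ids, imp.transform(g.dosages),
                         g.chrom, g.pos, g.ref, g.alt)
    return out


# ------------------------------------------------------------------------ IO
def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)  # gt_types: 0/1/2 = dosage, 3 = missing
    line_ids = np.asarray(vcf.samples, dtype=object)
    rows, mids, chroms, poss, refs, alts = [], [], [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = np.asarray(v.gt_types, dtype=float)
        gt[gt == 3] = np.nan
        rows.append(gt)
        mids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP record(s)")
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")
    g = GenotypeMatrix(line_ids, np.asarray(mids, dtype=object),
                       np.asarray(rows).T, chroms, poss, refs, alts)
    g.n_skipped_records = n_skipped
    return g


def _read_dosage_table(path: str, map_path: str | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    marker_ids = np.asarray(df.columns, dtype=object)
    if map_path is None:
        map_path = str(path) + ".map"
    try:
        mp = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        mp = mp.set_index("marker_id").loc[marker_ids]
        chrom, pos = mp["chrom"].to_numpy(), mp["pos"].to_numpy()
        ref, alt = mp["ref"].to_numpy(), mp["alt"].to_numpy()
    except FileNotFoundError:
        chrom = np.repeat("1", len(marker_ids))
        pos = np.arange(1, len(marker_ids) + 1)
        ref = np.repeat("A", len(marker_ids))
        alt = np.repeat("T", len(marker_ids))
    return GenotypeMatrix(np.asarray(df.index, dtype=object), marker_ids,
                          df.to_numpy(dtype=float), chrom, pos, ref, alt)


def read_genotypes(path: str, format: str = "dosage_table",
                   map_path: str | None = None) -> GenotypeMatrix:
    """Read a genotype panel from a VCF or a tab-separated dosage table.

    Marker order is file order.  For ``dosage_table`` a companion marker map
    (``<path>.map`` with columns marker_id/chrom/pos/ref/alt) is used when
    present; otherwise placeholder map metadata is generated.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "dosage_table":
        return _read_dosage_table(path, map_path)
    raise ValueError(f"unknown format {format!r}")


def write_dosage_table(g: GenotypeMatrix, path: str, map_path: str | None = None) -> None:
    """Write the tab-separated dosage table and its companion marker map."""
    df = pd.DataFrame(g.dosages, index=g.line_ids, columns=g.marker_ids)
    # integral dosages written without a decimal point so round trips are
    # bit-identical
    if not g.missing_mask.any() and np.all(np.mod(g.dosages, 1) == 0):
        df = df.astype(int)
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", na_rep="NA")
    if map_path is None:
        map_path = str(path) + ".map"
    pd.DataFrame({
        "marker_id": g.marker_ids, "chrom": g.chrom, "pos": g.pos,
        "ref": g.ref, "alt": g.alt,
    }).to_csv(map_path, sep="\t", index=False)
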