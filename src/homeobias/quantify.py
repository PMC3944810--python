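"""Gene-level read counting, the expressed-gene filter, and TMM normalization.

Counts are held gene x (library, category) with category one of A/D/X/N
(A-subgenome read, D-subgenome read, chimeric, uninformative).  Gene totals
per library (A+D+X+N) drive the expressed-gene filter; normalization uses
the trimmed mean of M-values (TMM) with the standard doubly-trimmed,
inverse-variance-weighted mean of log ratios.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .util import CATEGORIES, ConfigurationError, library_genotype

log = logging.getLogger(__name__)


@dataclass
class CountMatrix:
    """Gene x (library, category) integer read counts.

    ``counts`` has the gene ids as index and a two-level column MultiIndex
    (library, category).  ``unassigned`` records, per library, reads that
    overlapped no gene (or tied between two genes) and were dropped.
    """

    counts: pd.DataFrame
    unassigned: dict[str, int] = field(default_factory=dict)

    @property
    def libraries(self) -> list[str]:
        return list(self.counts.columns.get_level_values(0).unique())

    def gene_library_totals(self) -> pd.DataFrame:
        """Per-gene total assigned reads (A+D+X+N) per library."""
        return self.counts.T.groupby(level=0, sort=False).sum().T

    def library_totals(self) -> pd.Series:
        return self.gene_library_totals().sum(axis=0)

    def to_tsv(self, path) -> None:
        flat = self.counts.copy()
        flat.columns = [f"{lib}.{cat}" for lib, cat in flat.columns]
        flat.index.name = "gene_id"
        flat.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        flat = pd.read_csv(path, sep="\t", index_col=0)
        cols = [tuple(c.rsplit(".", 1)) for c in flat.columns]
        flat.columns = pd.MultiIndex.from_tuples(cols)
        return cls(counts=flat.astype(int))


def count_by_gene(
    reads: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Count categorized reads per gene for one library.

    ``reads`` needs columns chrom/start/end/category (0-based half-open
    aligned span); ``genes`` needs chrom/start/end/name with non-overlapping
    intervals per chromosome.  A read is assigned to the gene covering the
    largest number of its aligned bases; reads overlapping no gene, or tying
    between two genes, are dropped and tallied in the returned unassigned
    total.
    """
    gene_names = genes["name"].to_numpy()
    out = np.zeros((len(gene_names), len(CATEGORIES)), dtype=np.int64)
    row_of = {name: i for i, name in enumerate(gene_names)}
    cat_of = {c: i for i, c in enumerate(CATEGORIES)}
    unassigned = 0

    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}
    for chrom, sub in reads.groupby("chrom"):
        if chrom not in by_chrom:
            log.warning("reads on %s fall outside the gene model chromosomes", chrom)
            unassigned += len(sub)
            continue
        g = by_chrom[chrom]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        names = g["name"].to_numpy()
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()

        left = np.searchsorted(starts, rs, side="right") - 1

        def _overlap(idx: np.ndarray) -> np.ndarray:
            ok = (idx >= 0) & (idx < len(starts))
            ii = np.clip(idx, 0, len(starts) - 1)
            ov = np.minimum(re_, ends[ii]) - np.maximum(rs, starts[ii])
            return np.where(ok, np.maximum(ov, 0), 0)

        ov1 = _overlap(left)
        ov2 = _overlap(left + 1)
        tie = (ov1 == ov2) & (ov1 > 0)
        best_idx = np.where(ov1 >= ov2, left, left + 1)
        best_ov = np.maximum(ov1, ov2)
        assigned = (best_ov > 0) & ~tie
        unassigned += int((~assigned).sum())

        gi = np.array(
            [row_of[n] for n in names[np.clip(best_idx[assigned], 0, len(names) - 1)]],
            dtype=np.intp,
        )
        ci = np.array(
            [cat_of[c] for c in sub["category"].to_numpy()[assigned]], dtype=np.intp
        )
        np.add.at(out, (gi, ci), 1)

    df = pd.DataFrame(out, index=pd.Index(gene_names, name="gene_id"), columns=list(CATEGORIES))
    return df, unassigned


def build_count_matrix(
    reads_by_library: dict[str, pd.DataFrame], genes: pd.DataFrame
) -> CountMatrix:
    """Assemble the full gene x (library, category) matrix from per-library reads."""
    pieces = {}
    unassigned = {}
    for lib, reads in reads_by_library.items():
        df, un = count_by_gene(reads, genes)
        pieces[lib] = df
        unassigned[lib] = un
    counts = pd.concat(pieces, axis=1)
    return CountMatrix(counts=counts, unassigned=unassigned)


@dataclass
class FilterResult:
    matrix: CountMatrix
    expressed_flags: pd.DataFrame  # gene x library booleans (pre-filter universe)
    summary: dict


def filter_expressed(
    cm: CountMatrix, min_reads: int = 10, mode: str = "any"
) -> FilterResult:
    """Apply the expressed-gene filter.

    A gene counts as expressed in a library when its total assigned reads
    (A+D+X+N) reach ``min_reads`` there.  ``mode='any'`` retains genes
    expressed in at least one library (the operational definition used for
    all headline prevalence denominators); ``mode='all'`` is the stricter
    every-library reading.
    """
    if min_reads < 1:
        raise ConfigurationError(f"min_reads must be >= 1, got {min_reads}")
    if mode not in ("any", "all"):
        raise ConfigurationError(f"unknown filter mode {mode!r}")
    totals = cm.gene_library_totals()
    flags = totals >= min_reads
    keep = flags.any(axis=1) if mode == "any" else flags.all(axis=1)

    genotypes = {lib: library_genotype(lib) for lib in totals.columns}
    per_library = {lib: int(flags[lib].sum()) for lib in totals.columns}
    per_genotype = {}
    for geno in sorted(set(genotypes.values())):
        libs = [l for l, g in genotypes.items() if g == geno]
        per_genotype[geno] = int(flags[libs].any(axis=1).sum())
    summary = {
        "min_reads": min_reads,
        "mode": mode,
        "per_library": per_library,
        "per_genotype": per_genotype,
        "overall": int(flags.any(axis=1).sum()),
        "retained": int(keep.sum()),
        "input_genes": int(len(totals)),
    }
    filtered = CountMatrix(counts=cm.counts.loc[keep], unassigned=dict(cm.unassigned))
    return FilterResult(matrix=filtered, expressed_flags=flags, summary=summary)


@dataclass
class NormFactors:
    """TMM normalization factors for a set of count columns.

    ``effective_sizes`` are column totals multiplied by the factors; the
    factors are rescaled to geometric mean 1.
    """

    factors: pd.Series
    library_sizes: pd.Series
    ref_column: object
    logratio_trim: float
    sum_trim: float

    @property
    def effective_sizes(self) -> pd.Series:
        return self.library_sizes * self.factors

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "column": [c if isinstance(c, str) else ".".join(c) for c in self.factors.index],
                "tmm_factor": self.factors.to_numpy(),
                "library_size": self.library_sizes.to_numpy(),
                "effective_size": self.effective_sizes.to_numpy(),
            }
        )
        df.to_csv(path, sep="\t", index=False)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """Weighted trimmed-mean-of-M factor of one column against the reference.

    Genes with a zero in either column are excluded; M-values are trimmed
    symmetrically by ``logratio_trim`` total mass and average abundances by
    ``sum_trim``; weights are the inverse binomial (delta-method) variances
    of M.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > -1e10)
    log_r, abs_e, v = log_r[fin], abs_e[fin], v[fin]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    r_l = rankdata(log_r)
    r_s = rankdata(abs_e)
    keep = (r_l >= lo_l) & (r_l <= hi_l) & (r_s >= lo_s) & (r_s <= hi_s)
    if not keep.any():
        return 1.0
    w = 1.0 / v[keep]
    f = float(np.sum(log_r[keep] * w) / np.sum(w))
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    ref_column=None,
) -> NormFactors:
    """TMM factors for the columns of ``counts`` (genes x columns).

    The reference column is the one whose upper-quartile count fraction is
    closest to the mean upper-quartile fraction, unless given explicitly.
    Raises on an all-zero column, which has no defined scale.
    """
    if counts.shape[1] < 2:
        raise ConfigurationError("TMM needs at least two columns")
    x = counts.to_numpy(dtype=float)
    lib = x.sum(axis=0)
    zero = lib == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"column(s) with all-zero counts: {bad}")
    f75 = np.percentile(x, 75, axis=0) / lib
    if ref_column is None:
        ref = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        ref = counts.columns.get_loc(ref_column)
    factors = np.array(
        [
            _tmm_pair(x[:, k], x[:, ref], lib[k], lib[ref], logratio_trim, sum_trim)
            for k in range(x.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factors=pd.Series(factors, index=counts.columns),
        library_sizes=pd.Series(lib, index=counts.columns),
        ref_column=counts.columns[ref],
        logratio_trim=logratio_trim,
        sum_trim=sum_trim,
    )


def effective_sizes_for_model(cm: CountMatrix, mode: str = "library") -> pd.Series:
    """Per-(library, category) effective sizes used as GLM offsets.

    ``mode='library'`` runs TMM on the per-library total columns and applies
    each library's effective size to all four of its category columns (the
    default; robust when a category column, typically X, is empty).
    ``mode='library_category'`` normalizes every (library, category) column
    separately.
    """
    if mode == "library":
        nf = tmm_factors(cm.gene_library_totals())
        eff = nf.effective_sizes
        vals = [eff[lib] for lib, _cat in cm.counts.columns]
        return pd.Series(vals, index=cm.counts.columns)
    if mode == "library_category":
        nf = tmm_factors(cm.counts)
        return nf.effective_sizes
    raise ConfigurationError(f"unknown normalization mode {mode!r}")
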