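"""Per-gene Poisson models of genotype x read-category effects.

For every gene the counts Y across libraries and read categories follow a
log-linear Poisson model with treatment (genotype) effect T, category
(subgenome) effect G and their interaction TG, plus an offset for effective
library size:

    log E[Y] = offset + T + G + TG

The T x G interaction design is saturated in the (genotype, category) cell
means, so the maximum-likelihood fit has a closed form: each cell's rate is
its count total divided by its effective-size total (the fixed point of the
usual IRLS iteration).  Contrasts between two cells are tested by the
likelihood-ratio chi-square (df=1) against the model with those cells
merged; fold changes are computed from normalized cell means with a +0.5
stabilizer.  Benjamini-Hochberg control is applied per contrast family
across genes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import xlogy
from scipy.stats import chi2

from .quantify import CountMatrix
from .util import ConfigurationError, library_genotype

#: Contrasts of record: within-genotype homeolog bias and the mutation
#: effect on each homeolog.  Each maps to (numerator cell, denominator cell)
#: with cells given as (genotype, category).
CONTRASTS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "wtA_wtD": (("WT", "A"), ("WT", "D")),
    "LiA_LiD": (("Li2", "A"), ("Li2", "D")),
    "LiA_wtA": (("Li2", "A"), ("WT", "A")),
    "LiD_wtD": (("Li2", "D"), ("WT", "D")),
}


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} m * p_(j) / j over the ordered p-values, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class GeneGlmFit:
    """Saturated Poisson fit for one gene."""

    gene_id: str
    cells: list[tuple[str, str]]  # observed (genotype, category) cells
    rates: dict[tuple[str, str], float]  # ML cell rates (per unit effective size)
    y: np.ndarray
    sizes: np.ndarray  # exp(offset) per observation
    cell_of: list[tuple[str, str]]  # cell of each observation
    deviance: float
    converged: bool
    boundary_cells: list[tuple[str, str]]  # all-zero cells (rate at 0)

    def fitted(self) -> np.ndarray:
        return np.array([self.rates[c] for c in self.cell_of]) * self.sizes


def fit_gene_glm(
    y: np.ndarray,
    treatment: list[str],
    category: list[str],
    offsets: np.ndarray,
    gene_id: str = "",
) -> GeneGlmFit:
    """Maximum-likelihood Poisson fit of the saturated T x G cell-mean model.

    ``offsets`` are log effective library sizes.  Counts must be
    non-negative integers; all-zero cells sit on the boundary (rate 0) and
    are flagged.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be non-negative integers")
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    sizes = np.exp(offsets)
    cell_of = list(zip(treatment, category))
    cells = list(dict.fromkeys(cell_of))
    rates = {}
    boundary = []
    for cell in cells:
        mask = np.array([c == cell for c in cell_of])
        tot = y[mask].sum()
        rates[cell] = tot / sizes[mask].sum()
        if tot == 0:
            boundary.append(cell)
    mu = np.array([rates[c] for c in cell_of]) * sizes
    dev = float(2.0 * np.sum(xlogy(y, y) - xlogy(y, mu) - (y - mu)))
    return GeneGlmFit(
        gene_id=gene_id,
        cells=cells,
        rates=rates,
        y=y,
        sizes=sizes,
        cell_of=cell_of,
        deviance=dev,
        converged=True,
        boundary_cells=boundary,
    )


def _lrt_from_totals(y1, s1, y2, s2):
    """LRT statistic for equality of two Poisson cell rates (closed form).

    Only the two contrasted cells differ between the full and constrained
    fits, so the statistic reduces to their count and size totals.
    """
    ym = y1 + y2
    sm = s1 + s2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = 2.0 * (
            xlogy(y1, y1 / s1) + xlogy(y2, y2 / s2) - xlogy(ym, ym / sm)
        )
    return np.maximum(stat, 0.0)


@dataclass(frozen=True)
class ContrastResult:
    log2fc: float
    fc: float
    p: float
    lrt: float


def test_contrast(
    fit: GeneGlmFit,
    cell_num: tuple[str, str],
    cell_den: tuple[str, str],
    stabilizer: float = 0.5,
    scale: float | None = None,
) -> ContrastResult:
    """Likelihood-ratio test (df=1) of equality between two cells of a fit.

    The fold change is the ratio of normalized cell means (counts rescaled
    to a common size ``scale``, by default the geometric mean of the
    observation sizes) with ``stabilizer`` added to both means for
    reporting only.
    """
    for cell in (cell_num, cell_den):
        if cell not in fit.rates:
            raise ConfigurationError(f"contrast references absent cell {cell}")
    mask1 = np.array([c == cell_num for c in fit.cell_of])
    mask2 = np.array([c == cell_den for c in fit.cell_of])
    y1, s1 = fit.y[mask1].sum(), fit.sizes[mask1].sum()
    y2, s2 = fit.y[mask2].sum(), fit.sizes[mask2].sum()
    stat = float(_lrt_from_totals(y1, s1, y2, s2))
    p = float(chi2.sf(stat, df=1))
    if scale is None:
        scale = float(np.exp(np.mean(np.log(fit.sizes))))
    m1 = float(np.mean(fit.y[mask1] / fit.sizes[mask1]) * scale)
    m2 = float(np.mean(fit.y[mask2] / fit.sizes[mask2]) * scale)
    fc = (m1 + stabilizer) / (m2 + stabilizer)
    return ContrastResult(log2fc=float(np.log2(fc)), fc=float(fc), p=p, lrt=stat)


def run_dge(
    cm: CountMatrix,
    effective_sizes: pd.Series,
    contrasts: dict | None = None,
    alpha: float = 0.05,
    min_fold: float = 2.0,
    stabilizer: float = 0.5,
) -> pd.DataFrame:
    """Fit the per-gene model and test every contrast, vectorized over genes.

    Returns a tidy frame (gene_id, contrast, log2fc, fc, p, q, significant)
    where q is Benjamini-Hochberg within each contrast family and a gene is
    significant when q < ``alpha`` and the fold change is at least
    ``min_fold`` in either direction.  Identical, per gene, to
    `fit_gene_glm` + `test_contrast`.
    """
    contrasts = contrasts or CONTRASTS
    counts = cm.counts
    sizes = effective_sizes.reindex(counts.columns)
    if sizes.isna().any():
        raise ConfigurationError("effective_sizes missing for some columns")
    scale = float(np.exp(np.mean(np.log(sizes.to_numpy()))))

    cols_of_cell: dict[tuple[str, str], list] = {}
    for col in counts.columns:
        lib, cat = col
        cols_of_cell.setdefault((library_genotype(lib), cat), []).append(col)

    out = []
    for name, (cell1, cell2) in contrasts.items():
        for cell in (cell1, cell2):
            if cell not in cols_of_cell:
                raise ConfigurationError(
                    f"contrast {name} references absent cell {cell}"
                )
        c1, c2 = cols_of_cell[cell1], cols_of_cell[cell2]
        y1 = counts[c1].sum(axis=1).to_numpy(dtype=float)
        y2 = counts[c2].sum(axis=1).to_numpy(dtype=float)
        s1 = float(sizes[c1].sum())
        s2 = float(sizes[c2].sum())
        stat = _lrt_from_totals(y1, s1, y2, s2)
        p = chi2.sf(stat, df=1)
        m1 = (counts[c1] / sizes[c1]).mean(axis=1).to_numpy() * scale
        m2 = (counts[c2] / sizes[c2]).mean(axis=1).to_numpy() * scale
        fc = (m1 + stabilizer) / (m2 + stabilizer)
        q = bh_fdr(p)
        sig = (q < alpha) & (np.maximum(fc, 1.0 / fc) >= min_fold)
        out.append(
            pd.DataFrame(
                {
                    "gene_id": counts.index,
                    "contrast": name,
                    "log2fc": np.log2(fc),
                    "fc": fc,
                    "p": p,
                    "q": q,
                    "significant": sig,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def call_exclusive_expression(
    cm: CountMatrix, min_reads: int = 10
) -> pd.Series:
    """Per-gene genotype-exclusive expression calls.

    ``WT_only`` means expressed (>= min_reads in at least one WT library)
    and below threshold in every mutant library; symmetric for
    ``Li2_only``; otherwise ``both`` or ``neither``.
    """
    totals = cm.gene_library_totals()
    genos = {lib: library_genotype(lib) for lib in totals.columns}
    wt_libs = [l for l, g in genos.items() if g == "WT"]
    li_libs = [l for l, g in genos.items() if g == "Li2"]
    wt_expr = (totals[wt_libs] >= min_reads).any(axis=1)
    li_expr = (totals[li_libs] >= min_reads).any(axis=1)
    out = pd.Series("neither", index=totals.index, name="exclusive")
    out[wt_expr & ~li_expr] = "WT_only"
    out[li_expr & ~wt_expr] = "Li2_only"
    out[wt_expr & li_expr] = "both"
    return out
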