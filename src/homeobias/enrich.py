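"""Functional-category frequencies and between-subgenome Fisher enrichment.

Given the A-biased and D-biased gene sets and a gene -> functional-category
mapping (MapMan-BIN-style labels, possibly several per gene), this module
computes per-category frequencies as percentages of each set and tests
enrichment of each category between the two sets with the two-sided Fisher
exact test.  Raw p-values mirror the original uncorrected reporting;
Benjamini-Hochberg adjusted values are emitted alongside.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
from scipy.stats import fisher_exact

from .model import bh_fdr
from .util import percent


class CategoryMap:
    """gene id -> set of functional-category labels."""

    def __init__(self, table: pd.DataFrame):
        if not {"gene_id", "category"} <= set(table.columns):
            raise ValueError("category map needs gene_id and category columns")
        if (table["category"].astype(str).str.len() == 0).any():
            raise ValueError("empty category label")
        self.table = table[["gene_id", "category"]].drop_duplicates()
        self._by_gene: dict[str, set[str]] = {
            g: set(sub["category"]) for g, sub in self.table.groupby("gene_id")
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CategoryMap":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def universe(self) -> list[str]:
        return sorted(self.table["category"].unique())

    def categories_of(self, gene: str) -> set[str]:
        return self._by_gene.get(gene, set())


def category_frequencies(
    genes_a, genes_d, cmap: CategoryMap, floor_pct: float = 0.06
) -> pd.DataFrame:
    """Per-category counts and percentages of the A- and D-set sizes.

    A gene with several categories contributes once to each of them; an
    unmapped gene contributes to the set totals but to no category.
    Categories whose frequency stays below ``floor_pct`` in both sets are
    flagged (display floor), not removed.
    """
    genes_a, genes_d = list(genes_a), list(genes_d)
    if not genes_a or not genes_d:
        raise ValueError("both gene sets must be non-empty")
    rows = []
    for cat in cmap.universe:
        count_a = sum(cat in cmap.categories_of(g) for g in genes_a)
        count_d = sum(cat in cmap.categories_of(g) for g in genes_d)
        freq_a = percent(count_a, len(genes_a), 2)
        freq_d = percent(count_d, len(genes_d), 2)
        rows.append(
            {
                "category": cat,
                "count_A": count_a,
                "total_A": len(genes_a),
                "count_D": count_d,
                "total_D": len(genes_d),
                "freq_A_pct": freq_a,
                "freq_D_pct": freq_d,
                "above_floor": max(freq_a, freq_d) > floor_pct,
            }
        )
    return pd.DataFrame(rows)


def fisher_enrichment(
    count_a: int, total_a: int, count_d: int, total_d: int
) -> tuple[float, str]:
    """Two-sided Fisher exact p for one category between the two sets.

    Direction is the set with the higher category frequency ('A', 'D', or
    'none' when the proportions are identical).
    """
    for k, n in ((count_a, total_a), (count_d, total_d)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"invalid category count {k}/{n}")
    table = [[count_a, total_a - count_a], [count_d, total_d - count_d]]
    _, p = fisher_exact(table, alternative="two-sided")
    fa = count_a / total_a if total_a else 0.0
    fd = count_d / total_d if total_d else 0.0
    direction = "none" if fa == fd else ("A" if fa > fd else "D")
    return float(p), direction


def enrichment_table(
    genes_a, genes_d, cmap: CategoryMap, alpha: float = 0.05,
    floor_pct: float = 0.06,
) -> pd.DataFrame:
    """Frequencies plus Fisher p, BH q and significance flags per category.

    ``significant_raw`` uses the uncorrected p (the original convention);
    ``significant_adj`` uses the BH-adjusted q at the same level.
    """
    freq = category_frequencies(genes_a, genes_d, cmap, floor_pct=floor_pct)
    ps, dirs = [], []
    for _, row in freq.iterrows():
        p, d = fisher_enrichment(
            row["count_A"], row["total_A"], row["count_D"], row["total_D"]
        )
        ps.append(p)
        dirs.append(d)
    freq["direction"] = dirs
    freq["p"] = ps
    freq["q"] = bh_fdr(pd.Series(ps).to_numpy())
    freq["significant_raw"] = freq["p"] < alpha
    freq["significant_adj"] = freq["q"] < alpha
    return freq
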