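"""Homeolog expression-bias classification and mutation-effect analysis.

A gene is A-biased (D-biased) in a genotype when the within-genotype A/D
contrast is significant at the FDR threshold with at least a 2-fold
difference favouring that subgenome.  For wild-type-biased genes the
mutation effect is cross-classified from the per-homeolog mutant-vs-wild
contrasts into: changed in both homeologs, favoured homeolog up/down only,
or disfavoured homeolog up/down only.  Prevalence differences between
groups are compared by Pearson chi-square on 2x2 tables.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .util import ConfigurationError, percent

#: which within-genotype contrast carries the bias call for each genotype
BIAS_CONTRAST = {"WT": "wtA_wtD", "Li2": "LiA_LiD"}
#: mutation-effect contrast per homeolog (mutant vs wild type)
MUT_CONTRAST = {"A": "LiA_wtA", "D": "LiD_wtD"}

EFFECT_CLASSES = (
    "both_changed",
    "biased_homeolog_up",
    "biased_homeolog_down",
    "repressed_homeolog_up",
    "repressed_homeolog_down",
    "unchanged",
)


@dataclass
class BiasPrevalence:
    genotype: str
    biased: int
    expressed: int

    @property
    def pct(self) -> float:
        return percent(self.biased, self.expressed)


def classify_bias(
    results: pd.DataFrame, genotype: str, min_log2fc: float = 1.0
) -> tuple[pd.DataFrame, BiasPrevalence]:
    """Per-gene bias labels for one genotype from the A/D contrast results.

    ``results`` is the tidy output of `run_dge`.  A gene is
    A_biased when the contrast is significant and log2(A/D) >= min_log2fc,
    D_biased when significant and log2(A/D) <= -min_log2fc, else unbiased.
    """
    if genotype not in BIAS_CONTRAST:
        raise ConfigurationError(f"no bias contrast defined for {genotype!r}")
    contrast = BIAS_CONTRAST[genotype]
    sub = results[results["contrast"] == contrast]
    if sub.empty:
        raise ConfigurationError(f"no results for contrast {contrast}")
    label = np.full(len(sub), "unbiased", dtype=object)
    sig = sub["significant"].to_numpy()
    lfc = sub["log2fc"].to_numpy()
    label[sig & (lfc >= min_log2fc)] = "A_biased"
    label[sig & (lfc <= -min_log2fc)] = "D_biased"
    calls = pd.DataFrame(
        {
            "gene_id": sub["gene_id"].to_numpy(),
            "genotype": genotype,
            "label": label,
            "source_contrast": contrast,
        }
    )
    prevalence = BiasPrevalence(
        genotype=genotype,
        biased=int((label != "unbiased").sum()),
        expressed=int(len(sub)),
    )
    return calls, prevalence


def _direction(sig: bool, log2fc: float) -> str:
    if not sig:
        return "none"
    return "up" if log2fc > 0 else "down"


def classify_mutation_effect(
    bias_calls_wt: pd.DataFrame, results: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-classify mutation effects on wild-type-biased genes.

    Returns the per-gene classification and a summary table giving, per
    bias group (A_biased, D_biased), the percentage of genes changed in
    both homeologs and the up/down splits for the favoured ("biased") and
    disfavoured ("repressed") homeolog, with the group size as denominator.
    """
    for contrast in MUT_CONTRAST.values():
        if not (results["contrast"] == contrast).any():
            raise ConfigurationError(f"missing contrast {contrast}")
    wide = {}
    for sub_name, contrast in MUT_CONTRAST.items():
        sub = results[results["contrast"] == contrast].set_index("gene_id")
        wide[sub_name] = sub[["significant", "log2fc"]]

    biased = bias_calls_wt[bias_calls_wt["label"] != "unbiased"]
    rows = []
    for gene, wt_label in zip(biased["gene_id"], biased["label"]):
        sig_a = bool(wide["A"].loc[gene, "significant"])
        sig_d = bool(wide["D"].loc[gene, "significant"])
        dir_a = _direction(sig_a, wide["A"].loc[gene, "log2fc"])
        dir_d = _direction(sig_d, wide["D"].loc[gene, "log2fc"])
        fav, rep = ("A", "D") if wt_label == "A_biased" else ("D", "A")
        dir_fav = dir_a if fav == "A" else dir_d
        dir_rep = dir_d if fav == "A" else dir_a
        if sig_a and sig_d:
            cls = "both_changed"
        elif dir_fav != "none":
            cls = f"biased_homeolog_{dir_fav}"
        elif dir_rep != "none":
            cls = f"repressed_homeolog_{dir_rep}"
        else:
            cls = "unchanged"
        rows.append(
            (gene, wt_label, sig_a, sig_d, dir_a, dir_d, cls)
        )
    per_gene = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "wt_bias", "changed_in_A", "changed_in_D",
            "direction_A", "direction_D", "effect_class",
        ],
    )

    table_rows = []
    for group in ("A_biased", "D_biased"):
        grp = per_gene[per_gene["wt_bias"] == group]
        denom = len(grp)
        row = {"wt_bias": group, "n_genes": denom}
        for cls in EFFECT_CLASSES:
            k = int((grp["effect_class"] == cls).sum())
            row[f"{cls}_n"] = k
            row[f"{cls}_pct"] = percent(k, denom) if denom else float("nan")
        table_rows.append(row)
    summary = pd.DataFrame(table_rows)
    return per_gene, summary


def detect_reciprocal_bias(
    calls_wt: pd.DataFrame, calls_mut: pd.DataFrame
) -> list[str]:
    """Genes A-biased in one genotype and D-biased in the other.

    Requires a significant bias call in both genotypes; a mere sign flip
    without significance does not qualify.
    """
    wt = calls_wt.set_index("gene_id")["label"]
    mut = calls_mut.set_index("gene_id")["label"]
    common = wt.index.intersection(mut.index)
    wt, mut = wt[common], mut[common]
    flip = ((wt == "A_biased") & (mut == "D_biased")) | (
        (wt == "D_biased") & (mut == "A_biased")
    )
    return sorted(common[flip])


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    low_expected: bool  # any expected cell below 1


def compare_proportions(
    k1: int, n1: int, k2: int, n2: int, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square (df=1) comparing two proportions k1/n1 vs k2/n2.

    No continuity correction by default (the tables of interest have large
    counts); Yates correction is available via ``correction``.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n <= 0 or not 0 <= k <= n:
            raise ValueError(f"invalid proportion {k}/{n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        # degenerate margins: no information to compare
        return ChiSquareResult(chi2=0.0, df=1, p=1.0, low_expected=True)
    res = chi2_contingency(table, correction=correction)
    low = bool((res.expected_freq < 1).any())
    return ChiSquareResult(
        chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue), low_expected=low
    )
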