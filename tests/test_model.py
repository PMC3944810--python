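import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from homeobias.model import (
    CONTRASTS,
    bh_fdr,
    call_exclusive_expression,
    fit_gene_glm,
    run_dge,
    test_contrast as contrast_lrt,
)
from homeobias.quantify import CountMatrix

from .conftest import count_frame
from .oracles import bh_oracle


def _design(n_reps=2):
    treatment, category = [], []
    for geno in ("WT", "Li2"):
        for cat in ("A", "D"):
            treatment += [geno] * n_reps
            category += [cat] * n_reps
    return treatment, category


class TestGeneGlm:
    def test_saturated_fit_recovers_cell_means_with_equal_offsets(self):
        treatment, category = _design()
        y = np.array([10, 10, 10, 10, 20, 20, 20, 20])
        fit = fit_gene_glm(y, treatment, category, np.zeros(8))
        assert fit.rates[("WT", "A")] == pytest.approx(10.0)
        assert fit.rates[("Li2", "A")] == pytest.approx(20.0)
        # treatment effect exactly 2-fold, interaction exactly zero
        assert fit.rates[("Li2", "A")] / fit.rates[("WT", "A")] == pytest.approx(2.0)
        interaction = (fit.rates[("Li2", "A")] / fit.rates[("WT", "A")]) / (
            fit.rates[("Li2", "D")] / fit.rates[("WT", "D")]
        )
        assert interaction == pytest.approx(1.0)
        assert fit.deviance == pytest.approx(0.0, abs=1e-10)

    def test_equal_counts_give_zero_log2fc_everywhere(self):
        treatment, category = _design()
        y = np.full(8, 15)
        fit = fit_gene_glm(y, treatment, category, np.zeros(8))
        for cell1, cell2 in CONTRASTS.values():
            res = contrast_lrt(fit, cell1, cell2)
            assert res.log2fc == pytest.approx(0.0)
            assert res.p == pytest.approx(1.0)

    def test_fit_matches_statsmodels_glm_oracle(self, rng):
        """ML cell rates and LRT statistics agree with an independent
        Poisson-GLM fit (IRLS in statsmodels) to 1e-6."""
        import statsmodels.api as sm

        treatment, category = _design()
        offsets = np.log(rng.uniform(0.5, 2.0, size=8))
        y = rng.poisson(np.exp(offsets) * rng.uniform(5, 50, size=8))
        fit = fit_gene_glm(y, treatment, category, offsets)

        cells = sorted(set(zip(treatment, category)))
        x_full = np.array(
            [[1.0 if (t, g) == c else 0.0 for c in cells]
             for t, g in zip(treatment, category)]
        )
        full = sm.GLM(y, x_full, family=sm.families.Poisson(), offset=offsets).fit()
        np.testing.assert_allclose(fit.fitted(), full.fittedvalues, rtol=1e-6)

        # LRT against the model with the WT A and D cells merged
        merge = {("WT", "A"), ("WT", "D")}
        merged_cells = [c for c in cells if c not in merge] + ["WTmerged"]
        x_con = np.array(
            [
                [
                    1.0
                    if (c == "WTmerged" and (t, g) in merge) or (t, g) == c
                    else 0.0
                    for c in merged_cells
                ]
                for t, g in zip(treatment, category)
            ]
        )
        con = sm.GLM(y, x_con, family=sm.families.Poisson(), offset=offsets).fit()
        res = contrast_lrt(fit, ("WT", "A"), ("WT", "D"))
        assert res.lrt == pytest.approx(con.deviance - full.deviance, abs=1e-6)

    def test_all_zero_cell_sits_on_boundary(self):
        treatment, category = _design()
        y = np.array([0, 0, 10, 10, 5, 5, 5, 5])
        fit = fit_gene_glm(y, treatment, category, np.zeros(8))
        assert ("WT", "A") in fit.boundary_cells
        res = contrast_lrt(fit, ("WT", "A"), ("WT", "D"))
        # stabilizer caps the fold change; the test still detects the gap
        assert np.isfinite(res.log2fc)
        assert res.p < 0.01

    def test_non_integer_counts_rejected(self):
        treatment, category = _design()
        with pytest.raises(ValueError):
            fit_gene_glm(np.array([1.5] * 8), treatment, category, np.zeros(8))

    def test_missing_contrast_cell_rejected(self):
        fit = fit_gene_glm(
            np.array([5, 5]), ["WT", "WT"], ["A", "A"], np.zeros(2)
        )
        with pytest.raises(Exception):
            contrast_lrt(fit, ("WT", "A"), ("WT", "D"))


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_fdr(np.array([1.0, 1.0, 1.0])), 1.0)
        np.testing.assert_allclose(bh_fdr(np.array([0.3])), [0.3])
        assert bh_fdr(np.array([])).size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_matches_sort_based_oracle_exactly(self, pvals):
        ours = bh_fdr(np.array(pvals))
        expected = bh_oracle(pvals)
        np.testing.assert_allclose(ours, expected, rtol=0, atol=0)

    @settings(deadline=None, max_examples=100)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
    )
    def test_q_at_least_p_and_monotone_in_ordered_p(self, pvals):
        p = np.array(pvals)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


def _matrix_from_rates(rng, n_genes, mu_by_cell, libs=("WT_1", "WT_2", "Li2_1", "Li2_2")):
    data = {}
    for lib in libs:
        geno = lib.rsplit("_", 1)[0]
        for cat in ("A", "D", "X", "N"):
            mu = mu_by_cell.get((geno, cat), 1.0)
            data[(lib, cat)] = rng.poisson(mu, size=n_genes)
    return CountMatrix(counts=count_frame(data))


class TestRunDge:
    def test_matches_per_gene_path(self, rng):
        cm = _matrix_from_rates(
            rng, 30, {("WT", "A"): 40, ("WT", "D"): 15, ("Li2", "A"): 40, ("Li2", "D"): 30}
        )
        eff = pd.Series(
            rng.uniform(0.8, 1.2, size=len(cm.counts.columns)), index=cm.counts.columns
        )
        tidy = run_dge(cm, eff)
        scale = float(np.exp(np.mean(np.log(eff.to_numpy()))))
        treatment = [lib.rsplit("_", 1)[0] for lib, _ in cm.counts.columns]
        category = [cat for _, cat in cm.counts.columns]
        offsets = np.log(eff.to_numpy())
        for gene in cm.counts.index[:10]:
            y = cm.counts.loc[gene].to_numpy()
            fit = fit_gene_glm(y, treatment, category, offsets, gene_id=gene)
            for name, (c1, c2) in CONTRASTS.items():
                row = tidy[(tidy["gene_id"] == gene) & (tidy["contrast"] == name)]
                res = contrast_lrt(fit, c1, c2, scale=scale)
                assert row["p"].iloc[0] == pytest.approx(res.p, abs=1e-12)
                assert row["log2fc"].iloc[0] == pytest.approx(res.log2fc, rel=1e-12)

    def test_strong_homeolog_difference_detected(self, rng):
        """A 4-fold A/D difference at depth 100 is flagged significant."""
        cm = _matrix_from_rates(
            rng, 200, {("WT", "A"): 100, ("WT", "D"): 25, ("Li2", "A"): 100, ("Li2", "D"): 25}
        )
        eff = pd.Series(1.0, index=cm.counts.columns)
        tidy = run_dge(cm, eff)
        sub = tidy[tidy["contrast"] == "wtA_wtD"]
        assert sub["significant"].mean() > 0.95
        assert (sub["log2fc"] > 0).all()

    def test_significance_invariant_to_replicate_relabelling(self, rng):
        cm = _matrix_from_rates(
            rng, 50, {("WT", "A"): 60, ("WT", "D"): 20, ("Li2", "A"): 30, ("Li2", "D"): 30}
        )
        eff = pd.Series(1.0, index=cm.counts.columns)
        tidy = run_dge(cm, eff)
        # swap the two WT replicates wholesale
        swapped_cols = [
            ("WT_2" if l == "WT_1" else "WT_1" if l == "WT_2" else l, c)
            for l, c in cm.counts.columns
        ]
        cm2 = CountMatrix(
            counts=cm.counts.set_axis(
                pd.MultiIndex.from_tuples(swapped_cols), axis=1
            )
        )
        eff2 = pd.Series(1.0, index=cm2.counts.columns)
        tidy2 = run_dge(cm2, eff2)
        pd.testing.assert_series_equal(tidy["significant"], tidy2["significant"])


class TestExclusiveExpression:
    def _cm(self, wt, li):
        data = {}
        for lib, vals in (("WT_1", wt[0]), ("WT_2", wt[1]), ("Li2_1", li[0]), ("Li2_2", li[1])):
            data[(lib, "A")] = list(vals)
            for cat in ("D", "X", "N"):
                data[(lib, cat)] = [0] * len(vals)
        return CountMatrix(counts=count_frame(data))

    def test_classification_rules(self):
        cm = self._cm(
            wt=([50, 12, 20, 3], [60, 0, 20, 2]),
            li=([0, 0, 20, 1], [0, 9, 20, 0]),
        )
        labels = call_exclusive_expression(cm, min_reads=10)
        assert labels.tolist() == ["WT_only", "WT_only", "both", "neither"]
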