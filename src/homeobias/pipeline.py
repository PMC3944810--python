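"""End-to-end orchestration: simulate -> categorize -> count -> filter ->
normalize -> model -> bias -> enrichment, with a machine-readable report.

A run is fully determined by its configuration and seed: rerunning with the
same inputs reproduces the report byte for byte.  The two expensive stages
(read simulation and categorization) leave completion markers keyed by a
configuration hash, so a rerun in the same output directory resumes from
their cached outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bias as bias_mod
from . import enrich as enrich_mod
from .categorize import SnpIndex, categorize_alignments, summaries_to_table
from .model import call_exclusive_expression, run_dge
from .quantify import build_count_matrix, effective_sizes_for_model, filter_expressed
from .simulate import SimConfig, emit_reference, simulate_reads, simulate_truth
from .util import ConfigurationError, GENOTYPES, percent, sha256_file

log = logging.getLogger("homeobias.pipeline")

_ANALYSIS_KEYS = ("min_reads", "alpha", "min_fold", "norm_mode", "filter_mode")


@dataclass
class PipelineConfig:
    """Simulation design plus the analysis thresholds, all overridable."""

    sim: SimConfig = field(default_factory=lambda: SimConfig(n_genes=400, baseline_mean=80.0))
    min_reads: int = 10
    alpha: float = 0.05
    min_fold: float = 2.0
    norm_mode: str = "library"  # or "library_category"
    filter_mode: str = "any"  # or "all"

    @classmethod
    def from_toml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        """Flat key/value TOML: simulation and analysis keys side by side."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
        sim_kwargs = {}
        kwargs = {}
        for key, val in raw.items():
            if key in sim_fields:
                sim_kwargs[key] = tuple(val) if isinstance(val, list) else val
            elif key in _ANALYSIS_KEYS:
                kwargs[key] = val
            else:
                raise ConfigurationError(f"unknown config key {key!r}")
        if seed is not None:
            sim_kwargs["seed"] = seed
        return cls(sim=SimConfig(**sim_kwargs), **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _marker_ok(path: Path, digest: str) -> bool:
    return path.exists() and path.read_text().strip() == digest


def run_pipeline(
    config: PipelineConfig, outdir: str | Path, resume: bool = True
) -> dict:
    """Run every stage in order and return (and write) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    report: dict = {"config": config.to_dict(), "config_digest": digest}
    t0 = time.time()

    def _stage(name):
        log.info("stage %-12s at %6.1fs", name, time.time() - t0)

    # --- simulate ---------------------------------------------------------
    _stage("simulate")
    truth = simulate_truth(config.sim)
    sim_marker = outdir / "simulate.ok"
    libs = config.sim.libraries()
    sam_paths = {lib: outdir / f"{lib}.sam" for lib, *_ in libs}
    if not (resume and _marker_ok(sim_marker, digest)):
        paths = emit_reference(truth, outdir)
        for lib, geno, rep, _f in libs:
            simulate_reads(truth, geno, rep, sam_paths[lib])
        sim_marker.write_text(digest)
    else:
        paths = {
            "reference": outdir / "reference.fa",
            "genes": outdir / "genes.bed",
            "snp_index": outdir / "snp_index.tsv",
            "truth": outdir / "truth_genes.tsv",
            "category_map": outdir / "category_map.tsv",
        }
    report["files"] = {k: p.name for k, p in paths.items()}

    # --- categorize -------------------------------------------------------
    _stage("categorize")
    index = SnpIndex.from_tsv(paths["snp_index"])
    cat_marker = outdir / "categorize.ok"
    reads_paths = {lib: outdir / f"{lib}.reads.tsv" for lib, *_ in libs}
    reads_by_lib = {}
    summaries = []
    if resume and _marker_ok(cat_marker, digest):
        for lib, *_ in libs:
            reads_by_lib[lib] = pd.read_csv(reads_paths[lib], sep="\t")
        summary_table = pd.read_csv(outdir / "category_summary.tsv", sep="\t")
    else:
        for lib, *_ in libs:
            reads, summary = categorize_alignments(sam_paths[lib], index, library=lib)
            reads.to_csv(reads_paths[lib], sep="\t", index=False)
            reads_by_lib[lib] = reads
            summaries.append(summary)
        summary_table = summaries_to_table(summaries)
        summary_table.to_csv(outdir / "category_summary.tsv", sep="\t", index=False)
        cat_marker.write_text(digest)
    report["category_summary"] = {
        lib: {
            row["row"]: {"count": int(row["count"]), "pct": float(row["pct"])}
            for _, row in summary_table[summary_table["library"] == lib].iterrows()
        }
        for lib in summary_table["library"].unique()
    }

    # --- count ------------------------------------------------------------
    _stage("count")
    genes_bed = pd.read_csv(
        paths["genes"], sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
    )
    cm = build_count_matrix(reads_by_lib, genes_bed)
    cm.to_tsv(outdir / "counts.tsv")
    report["unassigned_reads"] = {k: int(v) for k, v in cm.unassigned.items()}

    # --- filter -----------------------------------------------------------
    _stage("filter")
    fres = filter_expressed(cm, min_reads=config.min_reads, mode=config.filter_mode)
    fres.matrix.to_tsv(outdir / "counts.filtered.tsv")
    expressed = dict(fres.summary)
    n_annot = config.sim.n_genes
    expressed["pct_per_genotype"] = {
        g: percent(k, n_annot) for g, k in fres.summary["per_genotype"].items()
    }
    expressed["pct_overall"] = percent(fres.summary["overall"], n_annot)
    report["expressed_genes"] = expressed

    # --- normalize --------------------------------------------------------
    _stage("normalize")
    eff = effective_sizes_for_model(fres.matrix, mode=config.norm_mode)
    pd.DataFrame(
        {
            "column": [".".join(c) for c in eff.index],
            "effective_size": eff.to_numpy(),
        }
    ).to_csv(outdir / "effective_sizes.tsv", sep="\t", index=False)

    # --- model ------------------------------------------------------------
    _stage("model")
    dge = run_dge(
        fres.matrix, eff, alpha=config.alpha, min_fold=config.min_fold
    )
    dge.to_csv(outdir / "dge.tsv", sep="\t", index=False)
    report["dge"] = {
        name: int(dge[(dge["contrast"] == name) & dge["significant"]].shape[0])
        for name in dge["contrast"].unique()
    }

    # --- bias -------------------------------------------------------------
    _stage("bias")
    calls = {}
    prevalences = {}
    for geno in GENOTYPES:
        c, prev = bias_mod.classify_bias(dge, geno)
        calls[geno] = c
        prevalences[geno] = prev
        c.to_csv(outdir / f"bias_calls.{geno}.tsv", sep="\t", index=False)
    report["bias_prevalence"] = {
        g: {"biased": p.biased, "expressed": p.expressed, "pct": p.pct}
        for g, p in prevalences.items()
    }
    pw, pm = prevalences["WT"], prevalences["Li2"]
    chi_bias = bias_mod.compare_proportions(
        pw.biased, pw.expressed, pm.biased, pm.expressed
    )
    report["chi_square_bias_reduction"] = dataclasses.asdict(chi_bias)

    effect_genes, effect_table = bias_mod.classify_mutation_effect(calls["WT"], dge)
    effect_genes.to_csv(outdir / "mutation_effect.tsv", sep="\t", index=False)
    effect_table.to_csv(outdir / "mutation_effect_summary.tsv", sep="\t", index=False)
    report["mutation_effect"] = {
        row["wt_bias"]: {
            "n_genes": int(row["n_genes"]),
            "both_changed_n": int(row["both_changed_n"]),
            "both_changed_pct": (
                float(row["both_changed_pct"]) if row["n_genes"] else None
            ),
        }
        for _, row in effect_table.iterrows()
    }
    ta = effect_table.set_index("wt_bias")
    if ta.loc["A_biased", "n_genes"] > 0 and ta.loc["D_biased", "n_genes"] > 0:
        chi_mut = bias_mod.compare_proportions(
            int(ta.loc["A_biased", "both_changed_n"]),
            int(ta.loc["A_biased", "n_genes"]),
            int(ta.loc["D_biased", "both_changed_n"]),
            int(ta.loc["D_biased", "n_genes"]),
        )
        report["chi_square_mutation_effect"] = dataclasses.asdict(chi_mut)

    report["reciprocal_bias_genes"] = bias_mod.detect_reciprocal_bias(
        calls["WT"], calls["Li2"]
    )
    report["exclusive_expression"] = {
        str(k): int(v)
        for k, v in call_exclusive_expression(fres.matrix, min_reads=config.min_reads)
        .value_counts()
        .items()
    }

    # --- enrich -----------------------------------------------------------
    _stage("enrich")
    cmap = enrich_mod.CategoryMap.from_tsv(paths["category_map"])
    genes_a = calls["WT"].loc[calls["WT"]["label"] == "A_biased", "gene_id"]
    genes_d = calls["WT"].loc[calls["WT"]["label"] == "D_biased", "gene_id"]
    if len(genes_a) and len(genes_d):
        enr = enrich_mod.enrichment_table(genes_a, genes_d, cmap, alpha=config.alpha)
        enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        report["enrichment_significant_raw"] = sorted(
            enr.loc[enr["significant_raw"], "category"]
        )
    else:
        report["enrichment_significant_raw"] = None

    # --- recovery against truth ------------------------------------------
    _stage("recovery")
    truth_frame = truth.to_frame().set_index("gene_id")
    wt_calls = calls["WT"].set_index("gene_id")["label"]
    truth_labels = truth_frame.loc[wt_calls.index, "bias_label_wt"]
    is_biased_true = truth_labels != "unbiased"
    is_biased_called = wt_calls != "unbiased"
    tp = int((is_biased_true & is_biased_called & (truth_labels == wt_calls)).sum())
    fn = int(is_biased_true.sum()) - tp
    fp = int((~is_biased_true & is_biased_called).sum())
    tn = int((~is_biased_true & ~is_biased_called).sum())
    report["recovery"] = {
        "n_truth_biased_expressed": int(is_biased_true.sum()),
        "sensitivity": round(tp / max(tp + fn, 1), 4),
        "specificity": round(tn / max(tn + fp, 1), 4),
    }

    # --- finalize ---------------------------------------------------------
    report["checksums"] = {
        p.name: sha256_file(p)
        for p in sorted(outdir.glob("*.tsv")) + sorted(outdir.glob("*.bed"))
    }
    (outdir / "report.json").write_text(
        json.dumps(report, sort_keys=True, indent=2, default=str) + "\n"
    )
    _stage("done")
    return report
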