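import numpy as np
import pandas as pd
import pysam
import pytest

from homeobias.categorize import (
    MalformedRecordError,
    SnpIndex,
    UnmappedReadError,
    categorize_alignments,
    categorize_read,
)
from homeobias.simulate import simulate_reads
from homeobias.util import CATEGORIES


@pytest.fixture(scope="module")
def index():
    # SNPs at 1-based positions 11 and 21 on chr1: D alleles C and G,
    # A alleles T and A.
    return SnpIndex(
        pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "pos": [11, 21],
                "d_allele": ["C", "G"],
                "a_allele": ["T", "A"],
            }
        )
    )


def _seq(length, subs):
    base = list("G" * length)
    for off, b in subs.items():
        base[off] = b
    return "".join(base)


class TestDecisionRule:
    def test_read_without_snp_overlap_is_uninformative(self, make_read, index):
        cat = categorize_read(make_read("ACGT" * 2, start=100), index)
        assert (cat.label, cat.n_sites) == ("N", 0)

    def test_single_a_allele_site_labels_a(self, make_read, index):
        read = make_read(_seq(15, {10: "T"}), start=0)
        cat = categorize_read(read, index)
        assert (cat.label, cat.a_votes, cat.d_votes) == ("A", 1, 0)

    def test_single_d_allele_site_labels_d(self, make_read, index):
        read = make_read(_seq(15, {10: "C"}), start=0)
        cat = categorize_read(read, index)
        assert (cat.label, cat.a_votes, cat.d_votes) == ("D", 0, 1)

    def test_sites_supporting_both_alleles_label_chimeric(self, make_read, index):
        read = make_read(_seq(25, {10: "T", 20: "G"}), start=0)
        cat = categorize_read(read, index)
        assert (cat.label, cat.a_votes, cat.d_votes, cat.n_sites) == ("X", 1, 1, 2)

    def test_third_base_at_only_site_is_uninformative_not_chimeric(
        self, make_read, index
    ):
        read = make_read(_seq(15, {10: "G"}), start=0)  # neither C nor T
        cat = categorize_read(read, index)
        assert (cat.label, cat.n_sites) == ("N", 1)

    def test_ambiguity_code_at_site_skips_the_site(self, make_read, index):
        read = make_read(_seq(15, {10: "N"}), start=0)
        cat = categorize_read(read, index)
        assert (cat.label, cat.n_sites) == ("N", 0)

    def test_deletion_over_site_skips_the_site(self, make_read, index):
        # 10M 2D 10M spanning ref 0..22: ref positions 10 and 20 both under
        # the alignment span, but 10..11 are deleted from the read.
        seq = _seq(20, {18: "A"})  # query offset 18 maps to ref 20 (A allele)
        read = make_read(seq, start=0, cigar=[(0, 10), (2, 2), (0, 10)])
        cat = categorize_read(read, index)
        assert (cat.label, cat.a_votes, cat.n_sites) == ("A", 1, 1)

    def test_unmapped_read_rejected(self, make_read, index):
        read = make_read("ACGT", start=0, flag=4)
        with pytest.raises(UnmappedReadError):
            categorize_read(read, index)

    def test_cigar_sequence_mismatch_rejected(self, make_read, index):
        read = make_read("ACGTACGT", start=0, cigar=[(0, 10)])
        with pytest.raises(MalformedRecordError):
            categorize_read(read, index)


class TestIndexValidation:
    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            SnpIndex(
                pd.DataFrame(
                    {"chrom": ["chr1"], "pos": [5], "d_allele": ["C"], "a_allele": ["C"]}
                )
            )

    def test_duplicate_positions_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SnpIndex(
                pd.DataFrame(
                    {
                        "chrom": ["chr1", "chr1"],
                        "pos": [5, 5],
                        "d_allele": ["C", "C"],
                        "a_allele": ["T", "G"],
                    }
                )
            )


@pytest.fixture(scope="module")
def categorized_library(small_truth, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("catlib")
    from homeobias.simulate import emit_reference

    paths = emit_reference(small_truth, outdir)
    sam = outdir / "WT_1.sam"
    simulate_reads(small_truth, "WT", 1, sam)
    index = SnpIndex.from_tsv(paths["snp_index"])
    reads, summary = categorize_alignments(sam, index, library="WT_1")
    return reads, summary, index, sam


class TestLibraryCategorization:
    def test_category_counts_conserve_mapped_total(self, categorized_library):
        _, summary, _, _ = categorized_library
        assert sum(summary.counts[c] for c in CATEGORIES) == summary.mapped_reads
        assert summary.mapped_reads == summary.total_reads  # all reads mapped

    def test_error_free_reads_never_misassigned(self, categorized_library):
        """Every read with at least one informative site is labelled with its
        true origin; the A<->D misassignment rate is exactly zero."""
        reads, summary, _, _ = categorized_library
        informative = reads[reads["n_sites"] > 0]
        assert len(informative) > 1000
        assert (informative["category"] == informative["true_origin"]).all()
        assert summary.counts["X"] == 0

    def test_reads_without_sites_are_n(self, categorized_library):
        reads, _, _, _ = categorized_library
        no_sites = reads[reads["n_sites"] == 0]
        assert (no_sites["category"] == "N").all()

    def test_allele_swap_symmetry(self, categorized_library):
        """Swapping the parental alleles in the index swaps A and D labels
        and leaves X and N untouched."""
        _, summary, index, sam = categorized_library
        _, swapped = categorize_alignments(sam, index.swapped(), library="WT_1")
        assert swapped.counts["A"] == summary.counts["D"]
        assert swapped.counts["D"] == summary.counts["A"]
        assert swapped.counts["X"] == summary.counts["X"]
        assert swapped.counts["N"] == summary.counts["N"]

    def test_category_tag_written_to_output_sam(
        self, categorized_library, tmp_path
    ):
        reads, _, index, sam = categorized_library
        out = tmp_path / "tagged.sam"
        categorize_alignments(sam, index, library="WT_1", out_sam=out)
        tags = []
        with pysam.AlignmentFile(str(out), "r") as fh:
            for rec in fh:
                tags.append(rec.get_tag("XC"))
        assert tags == reads["category"].tolist()

    def test_summary_percentages_use_one_decimal_of_total(self, categorized_library):
        _, summary, _, _ = categorized_library
        pct = summary.percentages()
        for c in CATEGORIES:
            assert pct[c] == round(100 * summary.counts[c] / summary.total_reads, 1)


def test_sequencing_error_misassignment_is_rare(tmp_path):
    """With error rate eps, only reads whose every informative base was
    corrupted can flip subgenome; the observed flip rate stays well below
    the single-site corruption rate."""
    from homeobias.simulate import SimConfig, emit_reference, simulate_truth

    cfg = SimConfig(
        n_genes=80, gene_length=600, baseline_mean=80.0, error_rate=0.01, seed=21
    )
    truth = simulate_truth(cfg)
    paths = emit_reference(truth, tmp_path)
    sam = tmp_path / "WT_1.sam"
    simulate_reads(truth, "WT", 1, sam)
    index = SnpIndex.from_tsv(paths["snp_index"])
    reads, _ = categorize_alignments(sam, index, library="WT_1")
    informative = reads[reads["n_sites"] > 0]
    flipped = (
        (informative["category"].isin(["A", "D"]))
        & (informative["category"] != informative["true_origin"])
    ).mean()
    assert flipped < 0.01 / 3 + 0.002
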