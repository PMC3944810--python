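"""SNP-based categorization of aligned reads into subgenome classes.

Each mapped read is labelled by its bases at homeologous SNP positions:

* ``A`` — every informative site supports the A-genome allele,
* ``D`` — every informative site supports the D-genome allele,
* ``X`` — chimeric: sites supporting both alleles,
* ``N`` — uninformative: no SNP overlapped, or no overlapped base matched
  either parental allele (a third base is evidence of sequencing error,
  not chimerism).

Sites whose read base is an ambiguity code, or that fall under deletions,
introns or soft clips, are treated as not overlapped.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .util import CATEGORIES, percent


class UnmappedReadError(ValueError):
    """Categorization was asked for a read without an alignment."""


class MalformedRecordError(ValueError):
    """SAM record whose CIGAR and sequence disagree."""


@dataclass(frozen=True)
class ReadCategory:
    label: str  # one of A, D, X, N
    a_votes: int
    d_votes: int
    n_sites: int


@dataclass
class CategorySummary:
    """Per-library read accounting in the style of a mapping-summary table."""

    library: str
    total_reads: int
    mapped_reads: int
    counts: dict[str, int]

    def percentages(self, ndigits: int = 1) -> dict[str, float]:
        """Category percentages against total reads, one-decimal convention."""
        out = {c: percent(self.counts[c], self.total_reads, ndigits) for c in CATEGORIES}
        out["mapped"] = percent(self.mapped_reads, self.total_reads, ndigits)
        return out

    def check_conservation(self) -> None:
        if sum(self.counts[c] for c in CATEGORIES) != self.mapped_reads:
            raise AssertionError(
                f"category counts do not sum to mapped reads in {self.library}"
            )

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages()
        rows = [("total_reads", self.total_reads, 100.0)]
        for c in CATEGORIES:
            rows.append((f"{c}_reads", self.counts[c], pct[c]))
        rows.append(("mapped_total", self.mapped_reads, pct["mapped"]))
        return pd.DataFrame(rows, columns=["row", "count", "pct"]).assign(
            library=self.library
        )


class SnpIndex:
    """Homeologous SNP index: 1-based reference positions with both alleles."""

    COLUMNS = ("chrom", "pos", "d_allele", "a_allele")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"SNP index missing columns: {sorted(missing)}")
        t = table[list(self.COLUMNS)].copy()
        for col in ("d_allele", "a_allele"):
            bad = ~t[col].isin(list("ACGT"))
            if bad.any():
                raise ValueError(f"non-ACGT {col} in SNP index")
        if (t["d_allele"] == t["a_allele"]).any():
            raise ValueError("SNP with identical parental alleles")
        if t.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate SNP positions")
        self.table = t.sort_values(["chrom", "pos"]).reset_index(drop=True)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.table.groupby("chrom"):
            self._by_chrom[chrom] = (
                sub["pos"].to_numpy() - 1,  # 0-based
                sub["d_allele"].to_numpy(),
                sub["a_allele"].to_numpy(),
            )

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SnpIndex":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def swapped(self) -> "SnpIndex":
        """Index with the parental alleles exchanged (for symmetry checks)."""
        t = self.table.rename(
            columns={"d_allele": "a_allele", "a_allele": "d_allele"}
        )
        return SnpIndex(t)

    def sites_in(
        self, chrom: str, start: int, end: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """SNPs with 0-based position in [start, end) on chrom."""
        if chrom not in self._by_chrom:
            empty = np.array([], dtype=int)
            return empty, empty.astype(str), empty.astype(str)
        pos0, d_all, a_all = self._by_chrom[chrom]
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        return pos0[lo:hi], d_all[lo:hi], a_all[lo:hi]


def _decide(a_votes: int, d_votes: int, n_sites: int) -> str:
    if n_sites == 0 or (a_votes == 0 and d_votes == 0):
        return "N"
    if a_votes > 0 and d_votes > 0:
        return "X"
    return "A" if a_votes > 0 else "D"


def categorize_read(read: pysam.AlignedSegment, index: SnpIndex) -> ReadCategory:
    """Label one mapped read by voting its bases at overlapped SNP sites."""
    if read.is_unmapped:
        raise UnmappedReadError(f"read {read.query_name} is unmapped")
    seq = read.query_sequence
    if seq is None:
        raise MalformedRecordError(f"read {read.query_name} has no sequence")
    expected = sum(
        ln for op, ln in (read.cigartuples or []) if op in (0, 1, 4, 7, 8)
    )
    if expected != len(seq):
        raise MalformedRecordError(
            f"read {read.query_name}: CIGAR consumes {expected} query bases "
            f"but SEQ has {len(seq)}"
        )

    chrom = read.reference_name
    pos0, d_all, a_all = index.sites_in(
        chrom, read.reference_start, read.reference_end
    )
    if pos0.size == 0:
        return ReadCategory("N", 0, 0, 0)

    cig = read.cigartuples
    if len(cig) == 1 and cig[0][0] in (0, 7, 8):
        offsets = pos0 - read.reference_start
        ref_to_query = dict(zip(pos0.tolist(), offsets.tolist()))
    else:
        ref_to_query = {
            rpos: qpos
            for qpos, rpos in read.get_aligned_pairs(matches_only=True)
        }

    a_votes = d_votes = n_sites = 0
    for p, d_base, a_base in zip(pos0.tolist(), d_all, a_all):
        q = ref_to_query.get(p)
        if q is None:
            continue  # deletion/intron/clip over the site
        base = seq[q].upper()
        if base not in "ACGT":
            continue  # ambiguity code: site treated as not overlapped
        n_sites += 1
        if base == a_base:
            a_votes += 1
        elif base == d_base:
            d_votes += 1
    return ReadCategory(_decide(a_votes, d_votes, n_sites), a_votes, d_votes, n_sites)


def categorize_alignments(
    sam_path: str | Path,
    index: SnpIndex,
    library: str | None = None,
    out_sam: str | Path | None = None,
    tag: str = "XC",
) -> tuple[pd.DataFrame, CategorySummary]:
    """Categorize every mapped primary record of a SAM file.

    Returns a per-read table (qname, chrom, start, end, category, votes and,
    when present, the simulator's true-origin XO tag) and a summary whose
    category counts always sum to the mapped total.  ``out_sam`` optionally
    writes a copy of the input with the category stored in ``tag``.
    """
    sam_path = Path(sam_path)
    lib = library or sam_path.stem
    rows = []
    counts = {c: 0 for c in CATEGORIES}
    total = mapped = 0
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        writer = (
            pysam.AlignmentFile(str(out_sam), "w", template=sam)
            if out_sam is not None
            else None
        )
        try:
            for read in sam:
                if read.is_secondary or read.is_supplementary:
                    continue
                total += 1
                if read.is_unmapped:
                    continue
                mapped += 1
                cat = categorize_read(read, index)
                counts[cat.label] += 1
                rows.append(
                    (
                        read.query_name,
                        read.reference_name,
                        read.reference_start,
                        read.reference_end,
                        cat.label,
                        cat.a_votes,
                        cat.d_votes,
                        cat.n_sites,
                        read.get_tag("XO") if read.has_tag("XO") else None,
                    )
                )
                if writer is not None:
                    read.set_tag(tag, cat.label, value_type="A")
                    writer.write(read)
        finally:
            if writer is not None:
                writer.close()
    reads = pd.DataFrame(
        rows,
        columns=[
            "qname", "chrom", "start", "end", "category",
            "a_votes", "d_votes", "n_sites", "true_origin",
        ],
    )
    summary = CategorySummary(
        library=lib, total_reads=total, mapped_reads=mapped, counts=counts
    )
    summary.check_conservation()
    return reads, summary


def summaries_to_table(summaries: list[CategorySummary]) -> pd.DataFrame:
    """Stack per-library summaries into one mapping-results table."""
    return pd.concat([s.to_frame() for s in summaries], ignore_index=True)
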