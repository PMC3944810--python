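"""Synthetic allotetraploid fiber-transcriptome generator.

Emulates a two-genotype (wild type vs a dominant short-fiber mutant) bulk
RNA-seq study of an AADD allopolyploid in which reads from both subgenome
copies of every gene co-align to a single (D-genome) reference.  Only the
homeologous SNPs scattered along each transcript make a read's subgenome of
origin observable, so the generator produces, from one seed:

* a reference sequence whose base at every homeologous SNP is the D allele,
* single-exon gene models laid out without overlap,
* a SNP index (position + the two parental alleles),
* aligned single-end reads in SAM with a tag recording true origin,
* a truth table of per-gene expected counts, bias labels and mutation
  effects, for recovery testing.

Expression structure: a configurable fraction of genes is truly A- or
D-biased in wild type (at least 2-fold between homeologs); the mutation
perturbs a larger fraction of D-biased than A-biased genes, mostly
repressing the favoured homeolog and de-repressing the disfavoured one.

Coordinates are 0-based half-open internally; emitted formats follow their
own conventions (BED half-open, SNP index 1-based).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .quantify import CountMatrix
from .util import (
    GENOTYPES,
    SUBGENOMES,
    ConfigurationError,
    InternalConsistencyError,
    library_name,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

FUNCTIONAL_CATEGORIES = (
    "cell_wall",
    "secondary_metabolism",
    "stress",
    "hormone_metabolism",
    "transcriptional_regulation",
    "protein",
    "signalling",
    "transport",
    "lipid_metabolism",
    "carbohydrates",
    "photosynthesis",
    "redox",
    "misc",
    "not_assigned",
)
# Categories over-represented among truly D-biased genes, mirroring the kind
# of between-subgenome functional skew the analysis is meant to detect.
_D_ENRICHED = ("secondary_metabolism", "stress")


def _as_range(value, name: str) -> tuple[float, float]:
    if np.isscalar(value):
        return (float(value), float(value))
    lo, hi = value
    if hi < lo:
        raise ConfigurationError(f"{name} range reversed: {value}")
    return (float(lo), float(hi))


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic dataset.

    Defaults emulate the study conditions: two genotypes x two biological
    replicates, 101-bp reads, roughly one homeologous SNP per 100 bp, about
    twice as many A-biased as D-biased genes, and a mutation that perturbs a
    larger share of D-biased (35.9%) than A-biased (26.5%) genes.
    """

    n_genes: int = 2000
    gene_length: int | tuple[int, int] = 1000
    snp_rate: float = 0.01  # expected homeologous SNPs per bp
    frac_biased_A: float = 0.10
    frac_biased_D: float = 0.055
    bias_log2fc: float | tuple[float, float] = (1.5, 3.5)  # |log2 mu_A/mu_D|, min >= 1
    frac_mut_affected_Abiased: float = 0.265
    frac_mut_affected_Dbiased: float = 0.359
    frac_mut_affected_unbiased: float = 0.05
    mut_log2fc: float | tuple[float, float] = (1.0, 2.5)  # effect magnitude
    mut_down_prob: float = 0.8  # P(favoured homeolog is repressed)
    mut_repressed_up_prob: float = 0.7  # P(disfavoured homeolog is induced)
    frac_silenced: float = 0.01  # expressed in WT only
    frac_activated: float = 0.01  # expressed in mutant only
    baseline_mean: float = 100.0  # expected reads/gene/library (both homeologs)
    baseline_log_sd: float = 0.4  # lognormal gene-to-gene depth spread
    libsize_factors: tuple[float, ...] = (1.0, 1.05, 1.02, 1.08)  # WT_1, WT_2, Li2_1, Li2_2
    error_rate: float = 0.002  # per-base sequencing error
    read_length: int = 101
    n_reps: int = 2
    n_chromosomes: int = 3
    intergenic_gap: int = 200
    chimera_rate: float = 0.0  # true mixed-allele reads; off by default
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_biased_A": self.frac_biased_A,
            "frac_biased_D": self.frac_biased_D,
            "frac_mut_affected_Abiased": self.frac_mut_affected_Abiased,
            "frac_mut_affected_Dbiased": self.frac_mut_affected_Dbiased,
            "frac_mut_affected_unbiased": self.frac_mut_affected_unbiased,
            "frac_silenced": self.frac_silenced,
            "frac_activated": self.frac_activated,
            "mut_down_prob": self.mut_down_prob,
            "mut_repressed_up_prob": self.mut_repressed_up_prob,
            "chimera_rate": self.chimera_rate,
        }
        for name, val in fracs.items():
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {val}")
        if self.frac_biased_A + self.frac_biased_D > 1.0:
            raise ConfigurationError("frac_biased_A + frac_biased_D must be <= 1")
        if self.snp_rate <= 0:
            raise ConfigurationError("snp_rate must be positive")
        if self.n_reps < 2:
            raise ConfigurationError("n_reps must be >= 2")
        if not 0.0 <= self.error_rate < 1.0:
            raise ConfigurationError("error_rate must be in [0, 1)")
        lo, _ = _as_range(self.bias_log2fc, "bias_log2fc")
        if lo < 1.0:
            raise ConfigurationError("bias_log2fc must be >= 1 (at least 2-fold)")
        if len(self.libsize_factors) != 2 * self.n_reps:
            raise ConfigurationError(
                "libsize_factors must give one factor per library "
                f"({2 * self.n_reps} expected, {len(self.libsize_factors)} given)"
            )
        if any(f <= 0 for f in self.libsize_factors):
            raise ConfigurationError("libsize_factors must be positive")

    def libraries(self) -> list[tuple[str, str, int, float]]:
        """(library, genotype, replicate, libsize_factor) in canonical order."""
        out = []
        k = 0
        for geno in GENOTYPES:
            for rep in range(1, self.n_reps + 1):
                out.append((library_name(geno, rep), geno, rep, self.libsize_factors[k]))
                k += 1
        return out


@dataclass
class TruthTable:
    """Ground truth for one simulated dataset."""

    config: SimConfig
    genes: pd.DataFrame  # gene_id, chrom, start, end, length
    mu: dict[tuple[str, str], np.ndarray]  # (genotype, subgenome) -> expected count
    bias_label_wt: np.ndarray
    bias_label_mut: np.ndarray
    mut_effect_A: np.ndarray  # signed log2 Li2/WT effect per homeolog
    mut_effect_D: np.ndarray
    snps: pd.DataFrame  # chrom, pos0, gene_id, offset, d_allele, a_allele
    chrom_seqs: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    categories: pd.DataFrame | None = None  # gene_id, category

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        df = self.genes.copy()
        for geno in GENOTYPES:
            for sub in SUBGENOMES:
                df[f"mu_{geno}_{sub}"] = self.mu[(geno, sub)]
        df["bias_label_wt"] = self.bias_label_wt
        df["bias_label_mut"] = self.bias_label_mut
        df["mut_effect_A"] = self.mut_effect_A
        df["mut_effect_D"] = self.mut_effect_D
        return df


def bias_label_from_mu(mu_a: np.ndarray, mu_d: np.ndarray) -> np.ndarray:
    """Truth bias labels from expected counts: at least 2-fold either way."""
    mu_a = np.asarray(mu_a, dtype=float)
    mu_d = np.asarray(mu_d, dtype=float)
    lab = np.full(mu_a.shape, "unbiased", dtype=object)
    lab[(mu_a >= 2.0 * mu_d) & (mu_a > 0)] = "A_biased"
    lab[(mu_d >= 2.0 * mu_a) & (mu_d > 0)] = "D_biased"
    return lab


def _draw(rng: np.random.Generator, rng_spec, size: int) -> np.ndarray:
    lo, hi = rng_spec
    if lo == hi:
        return np.full(size, lo)
    return rng.uniform(lo, hi, size=size)


def simulate_truth(config: SimConfig) -> TruthTable:
    """Draw the full ground truth (layout, expression, SNPs, sequence)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes

    if np.isscalar(config.gene_length):
        lengths = np.full(n, int(config.gene_length))
    else:
        lo, hi = config.gene_length
        lengths = rng.integers(int(lo), int(hi) + 1, size=n)

    # Gene layout: round-robin over chromosomes, consecutive with fixed gaps.
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_idx = np.arange(n) % config.n_chromosomes
    starts = np.zeros(n, dtype=np.int64)
    cursor = {c: config.intergenic_gap for c in range(config.n_chromosomes)}
    for i in range(n):
        c = chrom_idx[i]
        starts[i] = cursor[c]
        cursor[c] += lengths[i] + config.intergenic_gap
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i:05d}" for i in range(n)],
            "chrom": [chrom_names[c] for c in chrom_idx],
            "start": starts,
            "end": starts + lengths,
            "length": lengths,
        }
    )

    # Reference sequence per chromosome.
    chrom_seqs = {
        chrom_names[c]: rng.choice(_BASES, size=int(cursor[c]))
        for c in range(config.n_chromosomes)
    }

    # Wild-type expression: gene total split between homeologs by bias.
    totals = config.baseline_mean * rng.lognormal(
        mean=-0.5 * config.baseline_log_sd**2, sigma=config.baseline_log_sd, size=n
    )
    n_a = round(config.frac_biased_A * n)
    n_d = round(config.frac_biased_D * n)
    order = rng.permutation(n)
    a_idx = order[:n_a]
    d_idx = order[n_a : n_a + n_d]
    ratio = np.ones(n)  # mu_A / mu_D
    ratio[a_idx] = 2.0 ** _draw(rng, _as_range(config.bias_log2fc, "bias_log2fc"), n_a)
    ratio[d_idx] = 2.0 ** -_draw(rng, _as_range(config.bias_log2fc, "bias_log2fc"), n_d)
    mu_wt_a = totals * ratio / (1.0 + ratio)
    mu_wt_d = totals / (1.0 + ratio)

    # Mutation effects. For a biased gene the mutation, when it strikes,
    # changes both homeologs: the favoured copy mostly down, the
    # disfavoured copy mostly up.
    eff_a = np.zeros(n)
    eff_d = np.zeros(n)
    mut_range = _as_range(config.mut_log2fc, "mut_log2fc")

    def _biased_effects(idx: np.ndarray, frac: float, favoured: str) -> None:
        k = round(frac * len(idx))
        hit = rng.permutation(idx)[:k]
        fav_sign = np.where(rng.random(k) < config.mut_down_prob, -1.0, 1.0)
        rep_sign = np.where(rng.random(k) < config.mut_repressed_up_prob, 1.0, -1.0)
        fav_eff = fav_sign * _draw(rng, mut_range, k)
        rep_eff = rep_sign * _draw(rng, mut_range, k)
        if favoured == "A":
            eff_a[hit] = fav_eff
            eff_d[hit] = rep_eff
        else:
            eff_d[hit] = fav_eff
            eff_a[hit] = rep_eff

    _biased_effects(a_idx, config.frac_mut_affected_Abiased, "A")
    _biased_effects(d_idx, config.frac_mut_affected_Dbiased, "D")

    unbiased_idx = order[n_a + n_d :]
    k_u = round(config.frac_mut_affected_unbiased * len(unbiased_idx))
    shuffled_u = rng.permutation(unbiased_idx)
    hit_u = shuffled_u[:k_u]
    sign_u = np.where(rng.random(k_u) < 0.5, -1.0, 1.0)
    mag_u = _draw(rng, mut_range, k_u)
    eff_a[hit_u] = sign_u * mag_u
    eff_d[hit_u] = sign_u * mag_u

    mu_li_a = mu_wt_a * 2.0**eff_a
    mu_li_d = mu_wt_d * 2.0**eff_d

    # Genotype-exclusive genes, drawn from the untouched unbiased pool.
    rest = shuffled_u[k_u:]
    k_sil = round(config.frac_silenced * n)
    k_act = round(config.frac_activated * n)
    if k_sil + k_act > len(rest):
        raise ConfigurationError(
            "not enough unbiased, unaffected genes for the requested "
            "silenced/activated fractions"
        )
    sil = rest[:k_sil]
    act = rest[k_sil : k_sil + k_act]
    mu_li_a[sil] = 0.0
    mu_li_d[sil] = 0.0
    eff_a[sil] = -np.inf
    eff_d[sil] = -np.inf
    mu_wt_a[act] = 0.0
    mu_wt_d[act] = 0.0
    eff_a[act] = np.inf
    eff_d[act] = np.inf

    mu = {
        ("WT", "A"): mu_wt_a,
        ("WT", "D"): mu_wt_d,
        ("Li2", "A"): mu_li_a,
        ("Li2", "D"): mu_li_d,
    }

    # Homeologous SNPs: Poisson count per gene, uniform non-colliding
    # offsets; the reference base is the D allele, the A allele is any of
    # the other three bases.
    snp_rows = []
    for i in range(n):
        k = rng.poisson(config.snp_rate * lengths[i])
        k = min(k, lengths[i])
        if k == 0:
            continue
        offsets = np.sort(rng.choice(lengths[i], size=k, replace=False))
        chrom = genes["chrom"].iat[i]
        pos0 = starts[i] + offsets
        d_alleles = chrom_seqs[chrom][pos0]
        shift = rng.integers(1, 4, size=k)
        a_alleles = _BASES[(_BASE_INDEX[d_alleles.view(np.uint8)] + shift) % 4]
        for o, p, da, aa in zip(offsets, pos0, d_alleles, a_alleles):
            snp_rows.append(
                (chrom, int(p), genes["gene_id"].iat[i], int(o), da.decode(), aa.decode())
            )
    snps = pd.DataFrame(
        snp_rows, columns=["chrom", "pos0", "gene_id", "offset", "d_allele", "a_allele"]
    )

    # Functional categories, one per gene, with two categories skewed
    # toward truly D-biased genes.
    base_p = np.ones(len(FUNCTIONAL_CATEGORIES))
    base_p /= base_p.sum()
    boost_p = np.ones(len(FUNCTIONAL_CATEGORIES))
    for c in _D_ENRICHED:
        boost_p[FUNCTIONAL_CATEGORIES.index(c)] = 4.0
    boost_p /= boost_p.sum()
    is_d_biased = np.zeros(n, dtype=bool)
    is_d_biased[d_idx] = True
    cats = np.where(
        is_d_biased,
        rng.choice(FUNCTIONAL_CATEGORIES, size=n, p=boost_p),
        rng.choice(FUNCTIONAL_CATEGORIES, size=n, p=base_p),
    )
    categories = pd.DataFrame({"gene_id": genes["gene_id"], "category": cats})

    return TruthTable(
        config=config,
        genes=genes,
        mu=mu,
        bias_label_wt=bias_label_from_mu(mu_wt_a, mu_wt_d),
        bias_label_mut=bias_label_from_mu(mu_li_a, mu_li_d),
        mut_effect_A=eff_a,
        mut_effect_D=eff_d,
        snps=snps,
        chrom_seqs=chrom_seqs,
        categories=categories,
    )


def emit_reference(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    """Write reference FASTA, gene BED6, SNP-index TSV, truth and category TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genes": outdir / "genes.bed",
        "snp_index": outdir / "snp_index.tsv",
        "truth": outdir / "truth_genes.tsv",
        "category_map": outdir / "category_map.tsv",
    }

    with open(paths["reference"], "w") as fh:
        for chrom, seq in truth.chrom_seqs.items():
            fh.write(f">{chrom}\n")
            s = seq.tobytes().decode()
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    bed = truth.genes[["chrom", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = "+"
    bed.to_csv(paths["genes"], sep="\t", header=False, index=False)

    idx = truth.snps.copy()
    for _, row in idx.iterrows():
        ref_base = truth.chrom_seqs[row["chrom"]][row["pos0"]].decode()
        if row["d_allele"] != ref_base:
            raise InternalConsistencyError(
                f"SNP at {row['chrom']}:{row['pos0'] + 1} has d_allele "
                f"{row['d_allele']} but reference base {ref_base}"
            )
        if row["a_allele"] == row["d_allele"]:
            raise InternalConsistencyError(
                f"SNP at {row['chrom']}:{row['pos0'] + 1} has identical alleles"
            )
    out_idx = pd.DataFrame(
        {
            "chrom": idx["chrom"],
            "pos": idx["pos0"] + 1,
            "d_allele": idx["d_allele"],
            "a_allele": idx["a_allele"],
        }
    )
    out_idx.to_csv(paths["snp_index"], sep="\t", index=False)

    truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
    truth.categories.to_csv(paths["category_map"], sep="\t", index=False)
    return paths


def _sam_header(truth: TruthTable) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": chrom, "LN": int(len(seq))}
            for chrom, seq in truth.chrom_seqs.items()
        ],
    }


def simulate_reads(
    truth: TruthTable,
    genotype: str,
    replicate: int,
    out_sam: str | Path,
    seed: int | None = None,
) -> int:
    """Emit one library of aligned single-end reads as SAM; returns read count.

    Read counts per gene and homeolog are Poisson with the truth means times
    the library's size factor; starts are uniform; A-origin reads carry the
    A allele at every covered SNP; per-base errors are applied at the
    configured rate.  Each record carries an XO tag with the true origin.
    """
    config = truth.config
    libs = {(g, r): (name, f) for name, g, r, f in config.libraries()}
    if (genotype, replicate) not in libs:
        raise ConfigurationError(f"unknown library {genotype} replicate {replicate}")
    lib_name_, factor = libs[(genotype, replicate)]
    lib_index = [name for name, *_ in config.libraries()].index(lib_name_)
    rng = np.random.default_rng(
        seed if seed is not None else [config.seed, 1000 + lib_index]
    )

    read_len = config.read_length
    min_len = int(truth.genes["length"].min())
    if read_len > min_len:
        raise ConfigurationError(
            f"read_length {read_len} exceeds shortest gene length {min_len}"
        )

    snps_by_gene = {
        g: (sub["offset"].to_numpy(), sub["a_allele"].to_numpy(dtype="S1"),
            sub["d_allele"].to_numpy(dtype="S1"))
        for g, sub in truth.snps.groupby("gene_id")
    }
    gene_order = truth.genes.sort_values(["chrom", "start"]).index

    n_written = 0
    with pysam.AlignmentFile(str(out_sam), "w", header=_sam_header(truth)) as sam:
        for i in gene_order:
            gene_id = truth.genes["gene_id"].iat[i]
            chrom = truth.genes["chrom"].iat[i]
            gstart = int(truth.genes["start"].iat[i])
            glen = int(truth.genes["length"].iat[i])
            gene_seq = truth.chrom_seqs[chrom][gstart : gstart + glen]
            offsets, a_alleles, d_alleles = snps_by_gene.get(
                gene_id, (np.array([], dtype=int), np.array([], dtype="S1"),
                          np.array([], dtype="S1"))
            )

            blocks = []
            for origin in SUBGENOMES:
                mu = truth.mu[(genotype, origin)][i] * factor
                n_reads = rng.poisson(mu) if mu > 0 else 0
                if n_reads == 0:
                    continue
                starts_r = rng.integers(0, glen - read_len + 1, size=n_reads)
                reads = np.empty((n_reads, read_len), dtype="S1")
                for j, s in enumerate(starts_r):
                    reads[j] = gene_seq[s : s + read_len]
                if origin == "A" and offsets.size:
                    for o, aa in zip(offsets, a_alleles):
                        cover = (starts_r <= o) & (o < starts_r + read_len)
                        reads[cover, o - starts_r[cover]] = aa
                if config.chimera_rate > 0 and offsets.size:
                    other = d_alleles if origin == "A" else a_alleles
                    chim = np.nonzero(rng.random(n_reads) < config.chimera_rate)[0]
                    for j in chim:
                        s = starts_r[j]
                        cov = np.nonzero((offsets >= s) & (offsets < s + read_len))[0]
                        if cov.size < 2:
                            continue
                        brk = rng.integers(1, cov.size)
                        for c in cov[brk:]:
                            reads[j, offsets[c] - s] = other[c]
                if config.error_rate > 0:
                    err = rng.random((n_reads, read_len)) < config.error_rate
                    n_err = int(err.sum())
                    if n_err:
                        orig = _BASE_INDEX[reads[err].view(np.uint8)]
                        shift = rng.integers(1, 4, size=n_err)
                        reads[err] = _BASES[(orig + shift) % 4]
                blocks.append((origin, starts_r, reads))

            records = []
            for origin, starts_r, reads in blocks:
                for j, s in enumerate(starts_r):
                    records.append((int(s), origin, reads[j].tobytes().decode()))
            records.sort(key=lambda t: t[0])
            for j, (s, origin, seq) in enumerate(records):
                rec = pysam.AlignedSegment()
                rec.query_name = f"{gene_id}|{lib_name_}|{j}"
                rec.flag = 0
                rec.reference_id = sam.get_tid(chrom)
                rec.reference_start = gstart + s
                rec.mapping_quality = 60
                rec.cigartuples = [(0, read_len)]
                rec.query_sequence = seq
                rec.set_tag("XO", origin, value_type="A")
                sam.write(rec)
                n_written += 1
    return n_written


def _informative_fraction(glen: int, read_len: int, offsets: np.ndarray) -> float:
    """Fraction of valid start positions from which a read covers >= 1 SNP."""
    n_valid = glen - read_len + 1
    if offsets.size == 0 or n_valid <= 0:
        return 0.0
    starts = np.maximum(offsets - read_len + 1, 0)
    ends = np.minimum(offsets, n_valid - 1)
    covered = 0
    cur_s, cur_e = None, None
    for s, e in zip(starts, ends):
        if s > e:
            continue
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return covered / n_valid


def simulate_counts(truth: TruthTable, seed: int | None = None) -> CountMatrix:
    """Draw the gene x (library, category) count matrix directly from truth.

    This bypasses read emission: informative reads (those covering at least
    one SNP) land in their true subgenome category, the remainder in N, and
    chimeras (if configured) in X.  Sequencing error is not applied at this
    level, so categories are exact; use `simulate_reads` +
    the categorizer for the error-bearing path.
    """
    config = truth.config
    rng = np.random.default_rng(seed if seed is not None else [config.seed, 77])
    read_len = config.read_length
    offsets_of = {
        g: sub["offset"].to_numpy() for g, sub in truth.snps.groupby("gene_id")
    }
    empty = np.array([], dtype=int)
    p_info = np.array(
        [
            _informative_fraction(
                int(truth.genes["length"].iat[i]),
                read_len,
                offsets_of.get(truth.genes["gene_id"].iat[i], empty),
            )
            for i in range(len(truth.genes))
        ]
    )

    cols = {}
    for lib, geno, _rep, factor in config.libraries():
        mu_a = truth.mu[(geno, "A")] * factor
        mu_d = truth.mu[(geno, "D")] * factor
        chim = config.chimera_rate
        cols[(lib, "A")] = rng.poisson(mu_a * p_info * (1 - chim))
        cols[(lib, "D")] = rng.poisson(mu_d * p_info * (1 - chim))
        cols[(lib, "X")] = rng.poisson((mu_a + mu_d) * p_info * chim)
        cols[(lib, "N")] = rng.poisson((mu_a + mu_d) * (1 - p_info))
    counts = pd.DataFrame(
        cols, index=pd.Index(truth.genes["gene_id"], name="gene_id")
    )
    counts.columns = pd.MultiIndex.from_tuples(counts.columns)
    return CountMatrix(counts=counts, unassigned={})


def simulate_dataset(config: SimConfig, outdir: str | Path) -> dict:
    """Truth + reference files + one SAM per library; returns paths and counts."""
    truth = simulate_truth(config)
    paths = emit_reference(truth, outdir)
    outdir = Path(outdir)
    sam_paths = {}
    n_reads = {}
    for lib, geno, rep, _f in config.libraries():
        sam = outdir / f"{lib}.sam"
        n_reads[lib] = simulate_reads(truth, geno, rep, sam)
        sam_paths[lib] = sam
    return {"truth": truth, "paths": paths, "sam_paths": sam_paths, "n_reads": n_reads}
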