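# Methods

## Read categorization

A homeologous SNP index lists, for every diagnostic position on the
(D-genome) reference, the D allele (equal to the reference base) and the A
allele.  For each mapped read the CIGAR is walked to map reference SNP
positions to query offsets; only match/mismatch operations carry sites, so
positions under deletions, introns or soft clips are treated as not
overlapped, as are sites whose read base is an ambiguity code.  Votes are
unweighted — no base-quality weighting — and the label follows from the
vote pattern: `A` if only A-alleles were seen, `D` if only D-alleles, `X`
if both, `N` if no site was overlapped **or** no overlapped base matched
either allele.  The last clause is a deliberate choice: a third base at a
diagnostic site is evidence of sequencing error, not of a chimeric
molecule, so such reads are treated as uninformative rather than chimeric.
Mates of a pair are categorized independently; read counts, not fragment
counts, are the unit throughout.

Two invariants hold by construction and are enforced at run time: the
A+D+X+N counts always equal the mapped total, and swapping the parental
alleles in the index swaps the A and D labels while leaving X and N
unchanged.

## Counting, filtering, normalization

A read is assigned to the gene covering the largest number of its aligned
bases; reads overlapping no gene, or tying between two genes, are dropped
into an `unassigned` tally.  A gene is *expressed* when its total assigned
reads (A+D+X+N) reach 10 in at least one library; the at-least-one-sample
reading is the default because it is the operational definition behind all
prevalence denominators, with the stricter every-library reading available
as `mode="all"`.  Filtering uses gene totals, not per-category counts,
because it precedes the subgenome analysis.

TMM normalization follows the published weighted trimmed mean of M-values:
the reference column is the one whose upper-quartile count fraction is
closest to the mean upper-quartile fraction; genes with a zero in either
column of a pair are excluded; M-values are trimmed by 30% total mass and
average abundances by 5%; weights are the inverse delta-method (binomial)
variances of M; the resulting factors are rescaled to geometric mean 1.
Rank-based trimming uses average ranks on ties, matching the Bioconductor
implementation, against which the test suite cross-checks to 1e-6.

Offsets for the per-gene model can be built two ways.  The default runs
TMM on per-library totals and applies each library's effective size to all
four of its category columns.  A per-(library × category) mode also
exists, but it is not the default because the generator's default
configuration (no chimeras, no sequencing error at the counts level)
legitimately produces empty X columns, which have no defined scale; an
all-zero column raises an error rather than silently receiving a factor.

## The per-gene model

Counts for one gene follow a Poisson log-linear model with genotype (T),
read category (G, four levels A/D/X/N), their interaction, and log
effective library size as offset.  "Mixed model" notation sometimes used
for this design reduces to fixed effects here: the error term is the
Poisson variability itself and no random-effect grouping exists with two
replicates.  Because the T × G interaction design is saturated in the
(genotype, category) cell means, the maximum-likelihood fit is available
in closed form — each cell's rate is its count total over its
effective-size total, which is exactly the fixed point that iteratively
reweighted least squares would converge to.  The test suite verifies the
fitted means against an independent IRLS fit (statsmodels) to 1e-6.

Contrasts are tested by the likelihood ratio: the full model against the
model with the two contrasted cells merged, a chi-square with one degree
of freedom.  Only the contrasted cells differ between the two fits, so the
statistic reduces to their count and size totals,
`2[Y1 ln(Y1/S1) + Y2 ln(Y2/S2) − (Y1+Y2) ln((Y1+Y2)/(S1+S2))]` with
`0·ln 0 = 0`, which also behaves correctly at the boundary (an all-zero
cell).  The LRT was preferred over a Wald test precisely for that boundary
robustness.  Fold changes are reported from normalized cell means (counts
rescaled to the geometric-mean effective size) with a +0.5 stabilizer
added to both means — for reporting only; the test statistic never sees
the stabilizer.  Benjamini–Hochberg step-up FDR is applied separately per
contrast family, since gene counts are reported per comparison.  A gene is
significant in a contrast when q < 0.05 and the fold change is at least
2 in either direction.  Overdispersion is not modelled — the analysis is
Poisson by design; with two replicates per cell there is little
information to estimate a dispersion anyway, and the type-I calibration of
the LRT under the generator's Poisson truth is part of the acceptance
checks (rejection rate at 5% within [0.035, 0.065] over 2,500 null genes).

Exclusive-expression calls reuse the expressed-gene rule per genotype:
`WT_only` means at least 10 reads in some wild-type library and fewer than
10 in every mutant library, and symmetrically.

## Bias, mutation effects, comparisons

Bias calls come from the within-genotype A/D contrast: significant and
≥2-fold toward A (or D).  Prevalences are reported as biased/expressed
percentages rounded to one decimal.  For wild-type-biased genes the
mutant-vs-wild contrast of each homeolog is examined with the same global
q < 0.05 + 2-fold rule (no separate thresholds are defined for this step):
genes significant in both homeologs are `both_changed`; otherwise the
change is attributed to the favoured ("biased") or disfavoured
("repressed") homeolog with its direction.  Reciprocal-bias detection
requires a significant A-bias call in one genotype and a significant
D-bias call in the other — a sign flip without significance in both does
not qualify.

Proportions between groups (bias prevalence between genotypes; fraction of
both-changed genes between A- and D-biased groups) are compared by Pearson
chi-square on the 2×2 table, df = 1, without continuity correction by
default — all tables of interest have large counts, and the correction is
available as a flag.  Results carry a warning flag when any expected cell
falls below 1.

## Enrichment

Category frequencies are percentages of each biased set's size; a gene
with several category labels counts once per category, and unmapped genes
contribute to set totals only.  Enrichment between the A-set and D-set is
the two-sided Fisher exact test on the per-category 2×2 table.  Both raw
and BH-adjusted significance are emitted; the raw-p column mirrors the
original uncorrected reporting convention, with the adjusted column
alongside for transparency.  Categories below a 0.06% display floor are
flagged rather than dropped.  The between-set contrast is the implemented
background; whole-transcriptome backgrounds are out of scope.

## The synthetic generator

The generator emulates the study design rather than any particular
dataset: two genotypes × two replicates (library-size factors 1.00, 1.05,
1.02, 1.08 — the mutant libraries about 2% deeper), 101-bp single-end
reads emitted pre-aligned (the aligner is deliberately replaced, because
categorization, not alignment, is the computation under test), homeologous
SNPs placed per gene as a Poisson count at 0.01/bp with uniform
non-colliding offsets, A alleles drawn uniformly from the three
non-reference bases, and per-base sequencing error at 0.002.  Expression:
gene depth is lognormal around 100 expected reads per library
(gene-to-gene log-sd 0.4); 10% of genes are truly A-biased and 5.5%
D-biased (about twice as many A- as D-biased, as observed in fiber), with
|log2 A/D| drawn uniformly from [1.5, 3.5]; the mutation perturbs 26.5% of
A-biased and 35.9% of D-biased genes (the published fractions), mostly
repressing the favoured homeolog (p = 0.8) and inducing the disfavoured
one (p = 0.7) with magnitudes uniform in [1, 2.5] log2 units; 5% of
unbiased genes shift in both homeologs together; 1% of genes are silenced
in the mutant and 1% expressed only in the mutant.  Chimeric reads are off
by default (`chimera_rate = 0`): the data give no read-level chimera
model, so the default makes X-reads arise only from sequencing error, and
the optional rate exists purely to exercise the X code path.

Genes are single-exon, non-overlapping, laid round-robin across three
chromosomes — a small stand-in for the thirteen of the real reference.
Not emulated: splicing and multi-exon structure, indels, base-quality
strings, mapping ambiguity and alignment error, positional coverage bias,
and biological overdispersion beyond the lognormal gene-depth spread.
Passing recovery tests therefore demonstrates the correctness of the
categorization/counting/testing machinery under the model's own
assumptions, not robustness to alignment artifacts or extra-Poisson noise
in real libraries.

A counts-level path (`simulate_counts`) draws the gene × (library ×
category) matrix directly from the truth table — informative reads (those
whose start position covers at least one SNP) land in their true category,
the rest in N — and is used where read-level detail is irrelevant, e.g.
the 2,000-gene recovery and calibration runs.  The read-level path and the
categorizer are exercised together at smaller scale (a few hundred genes),
keeping the default test suite and the acceptance script to seconds.

## Numerical and design notes

* All coordinates are 0-based half-open internally; BED output is
  half-open, the SNP index 1-based.
* Ties in read-to-gene assignment are dropped, not arbitrated.
* `percent()` rounds to one decimal everywhere a summary percentage is
  printed, so recomputed table values compare exactly.
* Every random draw flows from `numpy.random.default_rng` seeded from the
  configuration; a fixed seed fixes every output byte, including SAM
  files (no timestamps or program lines in headers, stages write in
  deterministic order).  The pipeline report contains no wall-clock
  information; timings go to stderr.
* The pipeline caches its two expensive stages (read simulation,
  categorization) behind a configuration-hash marker; downstream stages
  are cheap and always recomputed.
* Known limitations: no probabilistic/posterior read assignment, no
  base-quality weighting, no overdispersion modelling (a deliberate match
  to the Poisson analysis), no paired-end mate reconciliation beyond
  independent categorization, and enrichment against a between-set rather
  than whole-genome background.
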