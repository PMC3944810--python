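# homeobias

Homeolog-resolved differential expression for allopolyploid RNA-seq.

## The problem

In an allotetraploid such as Upland cotton (*Gossypium hirsutum*, genome
AADD) every gene exists as a pair of homeologs — one copy from each
parental subgenome.  Bulk RNA-seq reads from both copies co-align to a
single reference, so measuring which subgenome a transcript came from
requires the fixed nucleotide differences (homeologous SNPs) between the
two subgenomes.  `homeobias` implements this analysis end to end for a
two-genotype design (a mutant and its near-isogenic wild type, two
biological replicates each):

1. **Read categorization** — every mapped read is labelled by its bases at
   homeologous SNP positions: `A` (all informative sites carry the
   A-genome allele), `D` (all carry the D-genome allele), `X` (chimeric:
   sites supporting both), or `N` (no SNP overlapped, or no base matched
   either allele).
2. **Counting and filtering** — reads are counted per gene per library per
   category; genes with fewer than 10 reads in every library are removed.
3. **Normalization** — trimmed mean of M-values (TMM): a doubly trimmed
   (30% on M, 5% on A), inverse-variance-weighted mean of log ratios
   against a reference column, rescaled to geometric mean 1.
4. **Per-gene model** — counts follow a Poisson log-linear model
   `log E[Y] = offset + T + G + TG`, with genotype `T`, read category `G`,
   their interaction, and log effective library size as offset.  Each
   contrast of interest (wtA/wtD, LiA/LiD, LiA/wtA, LiD/wtD) is tested by
   a likelihood-ratio chi-square (df = 1); Benjamini–Hochberg FDR is
   applied per contrast family.
5. **Bias and mutation-effect classification** — a gene is A-/D-biased in
   a genotype when the within-genotype contrast is significant (q < 0.05)
   with a ≥2-fold difference; for wild-type-biased genes the mutation
   effect is classified (changed in both homeologs, favoured homeolog
   up/down, disfavoured homeolog up/down, unchanged), prevalences are
   compared by Pearson chi-square, and reciprocal bias switches are
   detected.
6. **Enrichment** — functional-category (MapMan-BIN-style) frequencies of
   the A- and D-biased gene sets and two-sided Fisher exact tests between
   them.

Because raw sequencing data are not needed to exercise any of this, the
package ships a first-class synthetic-data generator that emulates the
study design: two genotypes × two replicates, per-gene per-homeolog
Poisson counts, a biased-gene fraction with ≥2-fold effects, a mutation
that perturbs more D-biased than A-biased genes, homeologous SNPs at low
density, and 101-bp reads carrying subgenome alleles plus sequencing
error, emitted as pre-aligned SAM together with a ground-truth table.

## Worked example

```sh
printf 'n_genes = 400\nbaseline_mean = 80.0\nseed = 5\n' > demo.toml
homeobias all --config demo.toml --outdir demo
```

prints

```
bias prevalence: WT 15.2% (61/400), Li2 13.5% (54/400)
report: demo/report.json
```

Of the 400 simulated genes, 61 (15.2%) are called subgenome-biased in
wild type but only 54 (13.5%) in the mutant — the generator's mutation
erodes bias, and the pipeline recovers that.  `demo/report.json` holds the
full machine-readable run report; for this run it shows a bias-label
recovery sensitivity of 0.98 and specificity of 1.00 against the
generator's truth table, per-library read-category summaries, expressed
gene counts, significant genes per contrast, the chi-square comparisons,
reciprocal-bias genes, and functional-category enrichment.  Intermediate
TSVs (`counts.tsv`, `dge.tsv`, `bias_calls.*.tsv`, `enrichment.tsv`, ...)
sit alongside it.  Each stage is also exposed as its own subcommand
(`simulate`, `categorize`, `count`, `filter`, `normalize`, `dge`, `bias`,
`enrich`) operating on plain TSV/SAM/BED/FASTA files, and as library
functions.

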