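# Methods

## Coordinate conventions and gene models

All internal coordinates are 0-based half-open. GFF3 (1-based closed) is
converted at the IO boundary; BED/BED12 are used natively. One canonical
transcript represents each gene: the transcript with the greatest summed
exon length, ties broken by lexicographically smallest transcript id. This
is a documented default, not a biological claim — annotation projects
differ in how they mark canonical isoforms, and a union-of-exons mode
(`isoform_policy="union"`) is available for users who prefer a flattened
model. Exons are stored 5′→3′ in gene orientation (exon 1 of a minus-strand
gene is the rightmost exon), and introns are derived as exon gaps, so the
exon-1/exon-3 indexing and intron indices used by every metric are
strand-aware by construction.

## Methylation classification

A two-stage procedure, both stages exact-binomial with Benjamini–Hochberg
adjustment:

1. **Site calls.** A covered cytosine (coverage ≥ `min_coverage`, default 3)
   is methylated iff the upper-tail probability of its methylated-read count
   under the non-conversion error rate (`error_rate`, default 0.005) is
   significant after BH adjustment across all sites. This absorbs bisulfite
   non-conversion without requiring a spike-in control.
2. **Gene tests.** Per context, a gene's count of methylated sites among
   covered sites is tested against the pooled genic average with binomial
   upper and lower tails, BH-adjusted across genes within each context/tail
   family. Sites are pooled across strands within the gene span.

Labels: teM requires CHG or CHH upper-tail significance and trumps
everything (TE-like methylation excludes a gene from the gbM set even when
its CG is elevated). gbM requires CG upper-tail significance without
non-CG elevation; a strict mode additionally demands CHG and CHH lower-tail
significance. UM requires *active* CG lower-tail significance — absence of
signal is not evidence of absence, so sparse genes fall into
`undetermined` (reason-coded, never an exception) rather than diluting the
UM group. Genes with fewer than `min_sites` (default 20) covered CG sites
are `undetermined`. Downstream group comparisons use only gbM and UM.

Defaults (`min_coverage=3`, `min_sites=20`, `alpha=0.05`,
`error_rate=0.005`) are conventional values for plant WGBS and are all
configurable.

## Long-read classification

Reads are assigned to the gene containing the largest share of their
aligned bases (strand-agnostic, so antisense reads remain assignable), with
at least 50% of aligned bases required inside the winning span and exact
ties unassigned. Per read:

- **antisense** ⟺ read strand ≠ gene strand; antisense reads are excluded
  from the TSS denominator (the TSS and antisense analyses are separate
  questions);
- **conventional TSS** ⟺ the 5′-most aligned position is at or 5′ of the
  exon-1 start plus a tolerance (default 0 bp, so a read starting 1 bp
  inside exon 1 is already nonconventional); for nonconventional reads we
  record whether the start falls in an annotated intron;
- **intron retention** ⟺ an intron is entirely contained in a single
  aligned block. Partial overlap is not retention: the conservative rule is
  unambiguous and exactly checkable against a per-base oracle.

Per-gene proportions use denominators of sense reads (TSS, retention;
intronless genes excluded from retention) or all assigned reads
(antisense), and are undefined below `min_reads` (default 5) to avoid
degenerate 0/1 proportions from single-read genes.

## Short-read metrics

Read–feature overlap is ≥1 bp, unstranded by default (configurable).
exon3/exon1 is a read-count ratio over the canonical transcript's first and
third exons in transcriptional order; a fragment overlapping both counts in
both — the ratio is a relative proxy, not an absolute rate. It is undefined
for genes with <3 exons or exon-1 count below `min_denominator` (default 1).
Intron RPKM counts a read once per gene regardless of how many introns it
touches, normalized by pooled intron length and library size; undefined for
intronless genes.

## Group comparisons

Wilcoxon rank-sum tests use exact enumeration when both samples are
tie-free with min(n) ≤ 8 and the tie-corrected normal approximation
otherwise. The proportion GLM is binomial with logit link on per-gene
(favorable, eligible−favorable) counts with covariates log10(gene length)
and log10(1 + assigned reads); logs are the conventional transforms for
length and expression covariates. Dispersion is estimated as Pearson
χ²/df (quasi-binomial, as in R), inflating standard errors when per-gene
proportions are overdispersed. (The scale is applied to the standard errors
directly; the `scale="X2"` option of statsmodels' GLM omits the binomial
variance weights for two-column endog and is not used.) The class contrast
is reported as UM minus gbM on the link scale, with Wald Z and two-sided
normal p; perfect separation is flagged in the result rather than raised.
Continuous metrics (exon3/exon1, intron RPKM) use the Wilcoxon path only.

In multi-condition short-read designs the methylation labels are always
computed from the designated reference (WT) methylome and propagated to all
conditions. This is the key analytical control: if a gbM–UM difference is
caused by methylation it should vanish in a mutant lacking gbM, whereas a
difference that persists is a property of the genes themselves.

## Synthetic-data generator

The generator emits the exact file formats the pipeline consumes (GFF3,
Bismark-style cytosine report, BED12, BED) plus a truth table. Defaults are
the study conditions the planted-effect checks assume: 2000 genes, 3–8
exons of 100–300 bp, introns of 80–200 bp, class priors 0.35/0.55/0.10
(gbM/UM/teM), mean 20 long reads per gene (gamma-Poisson, shape 5), and
planted per-class proportions — conventional TSS 0.81/0.78, antisense
0.0046/0.016, intron retention 0.149/0.106 (gbM/UM). Site-level methylation
rates (gbM: CG 0.70, non-CG at the 0.005 error floor; UM: all at the floor;
teM: 0.80/0.70/0.40) are chosen to be well separated from the pooled
background, as they are in real plant methylomes.

Mechanisms:

- **Methylome.** CG/CHG/CHH sites on a fixed grid (spacings 25/25/12 bp)
  with Poisson(10) coverage and binomial methylated counts at the class
  rate (floored at the non-conversion error rate).
- **Long reads.** Antisense with the class probability; sense reads start
  at the annotated TSS or, with the internal-start probability, at a
  uniform position 3′ of exon-1 start. Introns are retained independently,
  but only among the introns the read fully spans — an intron truncated by
  the read start cannot be observed as retained — with the per-intron rate
  solved per read as `q = 1 − (1 − p)^(1/k)` and `p` rescaled per gene for
  the (small) probability that a sense read spans no intron at all. The
  per-gene expectation of the measured retention proportion therefore
  equals the planted read-level value exactly, which is what the
  recovery checks assert. A read initiating inside a non-retained intron
  keeps the intron remainder in its first block (its donor site lies
  upstream of the read, so that stretch cannot be spliced).
- **Short reads.** Uniform exonic background (reads fully inside exons);
  an internal-initiation component in which each extra read draws its own
  internal start point and lands uniformly in the exonic space 3′ of it —
  the minimal mechanism that makes exon3/exon1 respond monotonically to
  the planted rate; and intron reads in proportion to the retention rate.

What the generator does **not** emulate: sequence content (no FASTA/FASTQ,
no alignment or mapping errors), 5′ degradation gradients, overlapping or
nested genes, alternative splicing beyond binary intron retention,
strand-asymmetric methylation, or expression–methylation correlations
beyond what is planted. Passing tests therefore demonstrate that the
statistical machinery recovers planted effects from correctly formatted
alignments; they do not certify robustness to mapping artifacts or
annotation errors in real data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full file-level pipeline
once at the default 2000-gene scale and use replicated simulation at the
classifier and GLM layers (200 replicates of 1000-gene null methylomes;
200 replicates of study-sized null GLM tables), which exercises the same
code paths the pipeline calls while keeping replication cheap. The
gene-property control uses 400 genes with a narrowed exon-length range
(150–250 bp) and deeper short-read coverage (150 reads/gene): the
exon3/exon1 baseline is a pure length ratio, and narrowing it lets the
qualitative persistence pattern be asserted with a rank test at moderate
scale. Ties in the Wilcoxon test fall back to the asymptotic path;
zero-coverage sites are rejected; empty groups raise before any model is
fitted; a saturated background (p_bg = 1) makes upper-tail tests never
significant, by construction rather than by special-casing.

## Known limitations

- Gene assignment ignores transcript compatibility: a read overlapping two
  genes is assigned by aligned-bp majority only.
- The TSS call trusts the annotation's exon-1 start; 5′-truncated library
  artifacts inflate the nonconventional class (in real Isoseq this is
  mitigated upstream by cap-trapping, which the generator does not model).
- The exon3/exon1 ratio is undefined for <3-exon genes and unstable for
  weakly covered exon 1; comparisons drop such genes, which can bias the
  retained set toward expressed genes.
- The quasi-binomial dispersion is a single global scale; gene-specific
  overdispersion structure is not modeled.
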