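# gbmti — gene-body methylation and transcript integrity

`gbmti` is an analysis pipeline for a question in plant epigenomics: does
gene-body methylation (gbM) — CG-context methylation inside transcribed
regions, found in a conserved subset of plant genes — protect transcripts
from aberrant initiation, antisense transcription and intron retention?
The package is aimed at researchers with a gene annotation, a bisulfite
methylome, and full-length long-read (Isoseq-style) and/or short-read
RNA-seq alignments who want to compare transcript-integrity metrics between
methylation-defined gene classes, plus a synthetic-data generator that makes
the whole pipeline testable end to end without any external download.

## What it computes

**Methylation classes.** Each covered cytosine site is called methylated by
an exact binomial test of its methylated-read count against the bisulfite
non-conversion rate (default 0.005), BH-adjusted across sites. Each gene is
then tested per context (CG, CHG, CHH) against the genic-average methylated
site fraction `p_bg[c]` with exact binomial upper/lower tails, BH-adjusted
across genes. Labels: **gbM** = CG above average, CHG/CHH not above;
**teM** = CHG or CHH above average (trumps gbM); **UM** = nothing above
average and CG significantly below; otherwise **undetermined**.

**Long-read metrics** (per gene, from spliced BED12 alignments):

- *conventional-TSS proportion* — sense reads whose 5′ end starts at or
  upstream of the start of exon 1, over all sense reads; reads starting
  after exon-1 start reflect internal initiation;
- *antisense proportion* — reads on the opposite strand of their gene, over
  all assigned reads (a proxy for reverse transcription);
- *intron-retention proportion* — sense reads with ≥1 annotated intron fully
  contained in one aligned block, over sense reads.

**Short-read metrics** (from BED intervals): the *exon3/exon1* read-count
ratio (elevated by cryptic initiation between exons 1 and 3) and *intron
RPKM* (reads overlapping introns per kb of pooled intron per million mapped
reads, a retention proxy).

**Group comparisons.** gbM vs UM genes are compared by Wilcoxon rank-sum
(exact for small tie-free samples) and, for proportion metrics, by a
quasi-binomial GLM with logit link,

```
logit P(favorable) ~ class + log10(length) + log10(1 + reads)
```

so that the class contrast (UM − gbM on the logit scale, Wald Z) is adjusted
for gene length and expression level. In multi-condition short-read designs
(WT vs a methylation mutant), genes are always grouped by their *reference
(WT) methylome* labels, so a gbM–UM difference that persists in a mutant
lacking gbM indicates a gene property rather than a methylation effect.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data. `analysis/01_simulate.py` writes a 2000-gene bundle with planted
per-class effect sizes, and `analysis/03_longread_analysis.py` prints:

```
prop_conventional_tss: gbM 0.8117 vs UM 0.7835 (n=678/1102); Wilcoxon p=2.35e-08; GLM contrast -0.183 (Z=-6.7, p=1.87e-11)
prop_antisense:        gbM 0.0039 vs UM 0.0155 (n=678/1103); Wilcoxon p=4.18e-24; GLM contrast 1.347 (Z=9.6, p=1.04e-21)
prop_intron_retained:  gbM 0.1476 vs UM 0.1037 (n=678/1102); Wilcoxon p=6.38e-27; GLM contrast -0.414 (Z=-12.7, p=5.64e-37)
```

The group means recover the planted values (0.81/0.78, 0.0046/0.016,
0.149/0.106) within sampling error, and every class contrast is detected.
The negative conventional-TSS contrast means the UM group is lower on the
logit scale (the sign convention is UM minus gbM).
`analysis/02_classify_methylation.py` reports 100% planted-label recovery
for the 2000 eligible genes, and `analysis/04_shortread_analysis.py`
demonstrates the WT-labels-in-mutant control: an exon3/exon1 difference
planted as a gene property shows up in both conditions
(`WT p=6.2e-05`, `mutant p=8.4e-05`).

The same functionality is exposed as a CLI (`gbmti simulate`,
`gbmti longread-metrics`, `gbmti shortread-metrics`, `gbmti compare`,
`gbmti run-longread`, `gbmti run-shortread`).

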