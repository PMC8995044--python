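"""Short-read RNA-seq coverage metrics.

Two per-gene proxies for transcript integrity:

- **exon3/exon1 ratio** — reads overlapping exon 3 divided by reads
  overlapping exon 1 (both in transcriptional order). Cryptic intragenic
  initiation between exons 1 and 3 inflates this ratio.
- **intron RPKM** — reads overlapping any intron of the gene (counted once
  per gene), normalized per kilobase of pooled intron length per million
  mapped reads; a proxy for intron retention.

Reads are plain genomic intervals (BED); overlap is >=1 bp under a
configurable strandedness policy (unstranded by default).
"""

from __future__ import annotations

from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationSet, GeneModel
from .intervals import GenomicInterval

STRANDEDNESS = ("unstranded", "sense", "antisense")


def load_short_reads(source: str | IO[str]) -> list[GenomicInterval]:
    """Read aligned intervals from BED (>=3 columns; strand from column 6)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    reads = []
    for line in lines:
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
        reads.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return reads


def _strand_ok(read: GenomicInterval, feature: GenomicInterval, policy: str) -> bool:
    if policy == "unstranded":
        return True
    if policy == "sense":
        return read.strand == feature.strand
    if policy == "antisense":
        return read.strand != feature.strand
    raise ValueError(f"unknown strandedness {policy!r}")


def count_reads_in_feature(
    reads: Iterable[GenomicInterval],
    feature: GenomicInterval,
    strandedness: str = "unstranded",
) -> int:
    """Number of reads with >=1 bp overlap with the feature."""
    return sum(
        1
        for r in reads
        if r.overlaps(feature) and _strand_ok(r, feature, strandedness)
    )


def count_reads_in_any(
    reads: Iterable[GenomicInterval],
    features: Sequence[GenomicInterval],
    strandedness: str = "unstranded",
) -> int:
    """Reads overlapping >=1 of the features, each read counted once."""
    if not features:
        return 0
    ref = features[0]
    return sum(
        1
        for r in reads
        if _strand_ok(r, ref, strandedness) and any(r.overlaps(f) for f in features)
    )


def feature_counts(
    reads: Sequence[GenomicInterval],
    gene: GeneModel,
    library_size: int,
    strandedness: str = "unstranded",
) -> dict:
    """Count reads on exon 1, exon 3 and the pooled introns of one gene."""
    near = [r for r in reads if r.chrom == gene.chrom and r.overlaps(gene.span)]
    exon1 = count_reads_in_feature(near, gene.exons[0], strandedness)
    exon3 = (
        count_reads_in_feature(near, gene.exons[2], strandedness)
        if gene.n_exons >= 3
        else 0
    )
    intron = count_reads_in_any(near, gene.introns, strandedness)
    return {
        "gene_id": gene.gene_id,
        "exon1_reads": exon1,
        "exon3_reads": exon3,
        "intron_reads": intron,
        "library_size": library_size,
    }


def exon3_exon1_ratio(counts: dict, gene: GeneModel, min_denominator: int = 1) -> float:
    """exon3 reads / exon1 reads; NaN when the gene has <3 exons or the
    exon-1 count is below ``min_denominator``."""
    if gene.n_exons < 3 or counts["exon1_reads"] < min_denominator:
        return float("nan")
    return counts["exon3_reads"] / counts["exon1_reads"]


def intron_rpkm(counts: dict, gene: GeneModel) -> float:
    """Intron reads per kb of pooled intron per million mapped reads; NaN
    for intronless genes."""
    if counts["library_size"] <= 0:
        raise ValueError(f"library_size must be positive, got {counts['library_size']}")
    ilen = gene.total_intron_length
    if ilen == 0:
        return float("nan")
    return counts["intron_reads"] * 1e9 / (counts["library_size"] * ilen)


def shortread_metrics_table(
    reads: Sequence[GenomicInterval],
    annotation: AnnotationSet,
    library_size: int,
    strandedness: str = "unstranded",
    min_denominator: int = 1,
) -> pd.DataFrame:
    """Per-gene coverage metrics over the whole annotation.

    Reads are bucketed by chromosome and sorted once so each gene only scans
    reads near its span.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for r in reads:
        by_chrom.setdefault(r.chrom, []).append(r)
    starts: dict[str, np.ndarray] = {}
    maxlen: dict[str, int] = {}
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start)
        starts[chrom] = np.array([r.start for r in rs])
        maxlen[chrom] = max(len(r) for r in rs)
    rows = []
    for gene in sorted(annotation, key=lambda g: g.gene_id):
        rs = by_chrom.get(gene.chrom, [])
        if rs:
            lo = int(
                np.searchsorted(
                    starts[gene.chrom], gene.span.start - maxlen[gene.chrom], "left"
                )
            )
            hi = int(np.searchsorted(starts[gene.chrom], gene.span.end, "left"))
            near = rs[lo:hi]
        else:
            near = []
        counts = feature_counts(near, gene, library_size, strandedness)
        counts["exon3_exon1_ratio"] = exon3_exon1_ratio(counts, gene, min_denominator)
        counts["intron_rpkm"] = intron_rpkm(counts, gene)
        counts["total_intron_length"] = gene.total_intron_length
        rows.append(counts)
    return pd.DataFrame(rows)
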