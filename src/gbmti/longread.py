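"""Full-length long-read (Isoseq-style) classification against gene models.

Each spliced read alignment is assigned to the gene carrying most of its
aligned bases, then classified three ways:

- **TSS class** (sense reads only): a read is *conventional* if its 5' end
  starts at or upstream of the start of exon 1 in gene orientation; a read
  starting after exon-1 start is nonconventional (internal initiation), and
  we record whether that internal start falls inside an annotated intron.
- **Antisense**: the read's strand differs from the gene's (a proxy for
  reverse transcription events).
- **Intron retention**: an annotated intron entirely contained within one
  aligned block was not spliced out.

Per-gene proportions aggregate these calls; a proportion is left undefined
(NaN) when its denominator has fewer than ``min_reads`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable, Optional

import pandas as pd

from .annotation import AnnotationSet, GeneModel
from .intervals import GenomicInterval


@dataclass(frozen=True)
class SplicedRead:
    """One long-read alignment: ordered aligned blocks plus strand."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.blocks, self.blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.read_id}: blocks overlap or unsorted")

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def read_start_5p(self) -> int:
        """5'-most aligned position in read orientation (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def aligned_bp(self) -> int:
        return sum(len(b) for b in self.blocks)


@dataclass(frozen=True)
class ReadCall:
    """Per-read classification relative to its assigned gene."""

    read_id: str
    gene_id: Optional[str]
    antisense: bool = False
    tss_conventional: Optional[bool] = None  # None for antisense/unassigned
    tss_in_intron: bool = False
    retained_introns: tuple[int, ...] = field(default=())


def parse_bed12_line(line: str) -> SplicedRead:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"BED12 needs 12 fields, got {len(f)}")
    chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
    n_blocks = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",") if x != ""]
    starts = [int(x) for x in f[11].rstrip(",").split(",") if x != ""]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(
            f"read {name}: blockCount={n_blocks} but "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    blocks = tuple(
        GenomicInterval(chrom, start + off, start + off + size, strand)
        for off, size in zip(starts, sizes)
    )
    return SplicedRead(read_id=name, chrom=chrom, strand=strand, blocks=blocks)


def load_read_alignments(source: str | IO[str]) -> list[SplicedRead]:
    """Read spliced alignments from BED12 (one primary alignment per line)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    reads = []
    for line in lines:
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        reads.append(parse_bed12_line(line))
    return reads


def assign_read_to_gene(
    read: SplicedRead, annotation: AnnotationSet, min_overlap_frac: float = 0.5
) -> Optional[str]:
    """Assign a read to the gene with maximal aligned-bp overlap.

    Candidates are genes whose span overlaps any block (strand-agnostic, so
    antisense reads stay assignable). Requires at least
    ``min_overlap_frac`` of the read's aligned bases inside the winning
    gene's span; an exact tie for the maximum yields no assignment.
    """
    candidates = annotation.query(read.chrom, read.start, read.end)
    if not candidates:
        return None
    overlaps = []
    for g in candidates:
        bp = sum(b.overlap_bp(g.span) for b in read.blocks)
        if bp > 0:
            overlaps.append((bp, g.gene_id))
    if not overlaps:
        return None
    overlaps.sort(key=lambda t: (-t[0], t[1]))
    best_bp = overlaps[0][0]
    if len(overlaps) > 1 and overlaps[1][0] == best_bp:
        return None
    if best_bp < min_overlap_frac * read.aligned_bp:
        return None
    return overlaps[0][1]


def classify_read(read: SplicedRead, gene: GeneModel, tss_tolerance: int = 0) -> ReadCall:
    """Classify one read against its assigned gene (see module docstring)."""
    if read.chrom != gene.chrom:
        raise ValueError(
            f"read {read.read_id} on {read.chrom} vs gene {gene.gene_id} on {gene.chrom}"
        )
    antisense = read.strand != gene.strand
    retained = tuple(
        i
        for i, intron in enumerate(gene.introns, start=1)
        if any(b.contains(intron) for b in read.blocks)
    )
    if antisense:
        return ReadCall(
            read_id=read.read_id,
            gene_id=gene.gene_id,
            antisense=True,
            tss_conventional=None,
            retained_introns=retained,
        )
    pos5 = read.read_start_5p
    anchor = gene.exon1_start_5p
    if gene.strand == "+":
        conventional = pos5 <= anchor + tss_tolerance
    else:
        conventional = pos5 >= anchor - tss_tolerance
    in_intron = (not conventional) and any(
        intron.contains_point(pos5) for intron in gene.introns
    )
    return ReadCall(
        read_id=read.read_id,
        gene_id=gene.gene_id,
        antisense=False,
        tss_conventional=conventional,
        tss_in_intron=in_intron,
        retained_introns=retained,
    )


def call_reads(
    reads: Iterable[SplicedRead],
    annotation: AnnotationSet,
    tss_tolerance: int = 0,
    min_overlap_frac: float = 0.5,
) -> list[ReadCall]:
    """Assign and classify every read; unassigned reads get gene_id None."""
    calls = []
    for read in reads:
        gid = assign_read_to_gene(read, annotation, min_overlap_frac)
        if gid is None:
            calls.append(ReadCall(read_id=read.read_id, gene_id=None))
        else:
            calls.append(classify_read(read, annotation[gid], tss_tolerance))
    return calls


def gene_longread_metrics(
    calls: Iterable[ReadCall], gene: GeneModel, min_reads: int = 5
) -> dict:
    """Aggregate read calls for one gene into proportion metrics.

    Denominators: conventional-TSS proportion over sense reads; antisense
    proportion over all assigned reads; intron-retention proportion over
    sense reads (undefined for intronless genes). A proportion whose
    denominator is below ``min_reads`` is NaN.
    """
    calls = [c for c in calls if c.gene_id == gene.gene_id]
    n_total = len(calls)
    sense = [c for c in calls if not c.antisense]
    n_sense = len(sense)
    n_anti = n_total - n_sense
    n_conv = sum(1 for c in sense if c.tss_conventional)
    n_retaining = sum(1 for c in sense if c.retained_introns)

    nan = float("nan")
    prop_conv = n_conv / n_sense if n_sense >= min_reads else nan
    prop_anti = n_anti / n_total if n_total >= min_reads else nan
    if gene.introns and n_sense >= min_reads:
        prop_ir = n_retaining / n_sense
    else:
        prop_ir = nan
    return {
        "gene_id": gene.gene_id,
        "n_reads": n_total,
        "n_reads_sense": n_sense,
        "n_reads_antisense": n_anti,
        "n_conventional": n_conv,
        "n_retaining": n_retaining,
        "prop_conventional_tss": prop_conv,
        "prop_antisense": prop_anti,
        "prop_intron_retained": prop_ir,
        "gene_length": gene.length,
        "expression_proxy": n_total,
    }


def longread_metrics_table(
    calls: Iterable[ReadCall], annotation: AnnotationSet, min_reads: int = 5
) -> pd.DataFrame:
    """Per-gene metrics table over all genes with >=1 assigned read."""
    by_gene: dict[str, list[ReadCall]] = {}
    for c in calls:
        if c.gene_id is not None:
            by_gene.setdefault(c.gene_id, []).append(c)
    rows = [
        gene_longread_metrics(cs, annotation[gid], min_reads)
        for gid, cs in sorted(by_gene.items())
    ]
    return pd.DataFrame(rows)


def read_calls_table(calls: Iterable[ReadCall]) -> pd.DataFrame:
    """Per-read calls as a flat table (for TSV export)."""
    return pd.DataFrame(
        {
            "read_id": c.read_id,
            "gene_id": c.gene_id if c.gene_id is not None else ".",
            "antisense": c.antisense,
            "tss_conventional": (
                "." if c.tss_conventional is None else str(c.tss_conventional)
            ),
            "tss_in_intron": c.tss_in_intron,
            "retained_introns": ",".join(map(str, c.retained_introns)) or ".",
        }
        for c in calls
    )
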