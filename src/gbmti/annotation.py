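"""Gene annotation backbone.

Parses GFF3 (gene / mRNA / exon with ``Parent`` links) into strand-aware
canonical gene models. Exons are kept in transcriptional (5'->3') order: for
a minus-strand gene, exon 1 is the rightmost exon in chromosome coordinates.
Introns are derived as the gaps between consecutive exons.

One canonical transcript represents each gene — by default the transcript
with the greatest summed exon length (ties broken by lexicographically
smallest transcript id); a union-of-exons mode is available for users who
prefer a flattened model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """A gene's canonical exon/intron structure.

    ``exons`` and ``introns`` are ordered 5'->3' in gene orientation; the
    span is the union of exons and introns.
    """

    gene_id: str
    span: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    introns: tuple[GenomicInterval, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: gene model needs >=1 exon")
        expected = derive_introns(self.exons)
        if self.introns != expected:
            object.__setattr__(self, "introns", expected)
        lo = min(e.start for e in self.exons)
        hi = max(e.end for e in self.exons)
        if (self.span.start, self.span.end) != (lo, hi):
            raise AnnotationError(f"{self.gene_id}: span does not match exon extent")

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def length(self) -> int:
        return len(self.span)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def total_intron_length(self) -> int:
        return sum(len(i) for i in self.introns)

    @property
    def exon1_start_5p(self) -> int:
        """5'-most position of exon 1 in gene orientation (0-based)."""
        first = self.exons[0]
        return first.start if self.strand == "+" else first.end - 1

    @property
    def end_3p(self) -> int:
        """3'-most position of the gene (0-based)."""
        return self.span.end - 1 if self.strand == "+" else self.span.start


def derive_introns(exons: Iterable[GenomicInterval]) -> tuple[GenomicInterval, ...]:
    """Gaps between consecutive exons, in the same 5'->3' order as the exons.

    Accepts exons in gene orientation (minus-strand genes list the rightmost
    exon first). Raises on overlapping exons.
    """
    exons = tuple(exons)
    if not exons:
        raise AnnotationError("no exons")
    if len(exons) == 1:
        return ()
    strand = exons[0].strand
    by_chrom = sorted(exons, key=lambda e: e.start)
    for a, b in zip(by_chrom, by_chrom[1:]):
        if b.start < a.end:
            raise AnnotationError(f"overlapping exons at {a} / {b}")
    gaps = [
        GenomicInterval(a.chrom, a.end, b.start, strand)
        for a, b in zip(by_chrom, by_chrom[1:])
    ]
    if strand == "-":
        gaps.reverse()
    return tuple(gaps)


def select_canonical(transcripts: Mapping[str, list[tuple[int, int]]]) -> str:
    """Pick the canonical transcript id: largest summed exon length, then
    lexicographically smallest id."""
    if not transcripts:
        raise AnnotationError("no transcripts to select from")
    return min(
        transcripts,
        key=lambda tid: (-sum(e - s for s, e in transcripts[tid]), tid),
    )


class AnnotationSet:
    """Gene models plus a per-chromosome interval index for overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise AnnotationError(f"duplicate gene id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.span.start, g.span.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def query(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose span overlaps [start, end) on chrom."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in tree.overlap(start, end)]


def _build_gene(
    gene_id: str, chrom: str, strand: str, exons_chrom_order: list[tuple[int, int]]
) -> GeneModel:
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons_chrom_order)]
    if strand == "-":
        ivs.reverse()
    span = GenomicInterval(
        chrom, min(e.start for e in ivs), max(e.end for e in ivs), strand
    )
    return GeneModel(gene_id=gene_id, span=span, exons=tuple(ivs))


def _validate_gff3_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise AnnotationError(
                f"malformed GFF3 at line {lineno}: expected 9 tab-separated "
                f"fields, got {len(fields)}"
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError as exc:
            raise AnnotationError(
                f"malformed GFF3 at line {lineno}: non-integer coordinates"
            ) from exc
        if start < 1 or end < start:
            raise AnnotationError(
                f"malformed GFF3 at line {lineno}: bad coordinate range {start}-{end}"
            )


def load_annotation(source: str | IO[str], isoform_policy: str = "canonical") -> AnnotationSet:
    """Parse GFF3 text (path or stream) into an :class:`AnnotationSet`.

    GFF3 1-based closed coordinates become 0-based half-open. Genes whose
    transcripts carry no exons are skipped with a warning; exon features
    whose Parent does not resolve to a transcript are skipped with a warning.
    """
    if isoform_policy not in ("canonical", "union"):
        raise ValueError(f"unknown isoform policy {isoform_policy!r}")
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    _validate_gff3_lines(text)
    db = gffutils.create_db(
        text,
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    transcript_types = ("mRNA", "transcript")
    known_parents = set()
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exon_sets: dict[str, list[tuple[int, int]]] = {}
        for t in db.children(gene, featuretype=transcript_types, level=1):
            known_parents.add(t.id)
            exons = [(f.start - 1, f.end) for f in db.children(t, featuretype="exon")]
            if exons:
                exon_sets[t.id] = sorted(exons)
            else:
                logger.warning("transcript %s of gene %s has no exons", t.id, gene.id)
        if not exon_sets:
            logger.warning("gene %s skipped: no transcript with exons", gene.id)
            continue
        if isoform_policy == "union":
            merged: list[tuple[int, int]] = []
            for s, e in sorted(x for exons in exon_sets.values() for x in exons):
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            chosen = merged
        else:
            chosen = exon_sets[select_canonical(exon_sets)]
        models.append(_build_gene(gene.id, gene.seqid, gene.strand, chosen))
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not any(p in known_parents for p in parents):
            logger.warning(
                "exon at %s:%d-%d has no resolvable transcript parent; skipped",
                exon.seqid, exon.start, exon.end,
            )
    return AnnotationSet(models)


def write_gff3(annotation: AnnotationSet, stream: IO[str]) -> None:
    """Write gene/mRNA/exon features, 1-based closed, round-trip safe."""
    stream.write("##gff-version 3\n")
    for g in annotation:
        s, e = g.span.start + 1, g.span.end
        stream.write(
            f"{g.chrom}\tgbmti\tgene\t{s}\t{e}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        tid = f"{g.gene_id}.1"
        stream.write(
            f"{g.chrom}\tgbmti\tmRNA\t{s}\t{e}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}\n"
        )
        for ex in sorted(g.exons, key=lambda x: x.start):
            stream.write(
                f"{g.chrom}\tgbmti\texon\t{ex.start + 1}\t{ex.end}\t.\t{g.strand}\t.\t"
                f"Parent={tid}\n"
            )


def gene_table(annotation: AnnotationSet) -> pd.DataFrame:
    """Per-gene summary table for inspection."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "start": g.span.start,
            "end": g.span.end,
            "strand": g.strand,
            "n_exons": g.n_exons,
            "length": g.length,
        }
        for g in annotation
    ]
    return pd.DataFrame(rows)
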