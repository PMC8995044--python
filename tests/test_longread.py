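"""Long-read classification: parsing, gene assignment, TSS/antisense/
retention calls, per-gene aggregation — checked against a brute-force
per-base oracle."""

import io
import math

import numpy as np
import pytest

from gbmti.annotation import AnnotationSet
from gbmti.intervals import GenomicInterval
from gbmti.longread import (
    ReadCall,
    SplicedRead,
    assign_read_to_gene,
    classify_read,
    gene_longread_metrics,
    load_read_alignments,
    parse_bed12_line,
)

from conftest import make_gene

# ------------------------------------------------------------------- oracle


def brute_force_classify(read: SplicedRead, gene, tss_tolerance: int = 0) -> ReadCall:
    """Per-base reimplementation with explicit position sets."""
    antisense = read.strand != gene.strand
    block_sets = [set(range(b.start, b.end)) for b in read.blocks]
    retained = tuple(
        i
        for i, intron in enumerate(gene.introns, start=1)
        if any(set(range(intron.start, intron.end)) <= bs for bs in block_sets)
    )
    if antisense:
        return ReadCall(read.read_id, gene.gene_id, True, None, False, retained)
    # gene-body positions ordered 5'->3'; conventional = the 5' start sits
    # in the explicit at-or-upstream-of-anchor position set
    oriented = list(range(gene.span.start, gene.span.end))
    if gene.strand == "-":
        oriented.reverse()
    pos5 = read.read_start_5p
    upstream_of_gene = (
        pos5 < gene.span.start if gene.strand == "+" else pos5 >= gene.span.end
    )
    conventional = upstream_of_gene or pos5 in set(oriented[: tss_tolerance + 1])
    intron_bases = set()
    for intron in gene.introns:
        intron_bases |= set(range(intron.start, intron.end))
    in_intron = (not conventional) and pos5 in intron_bases
    return ReadCall(read.read_id, gene.gene_id, False, conventional, in_intron, retained)


def random_gene(rng, chrom="c"):
    n_exons = int(rng.integers(1, 5))
    bounds = np.cumsum(rng.integers(2, 40, size=2 * n_exons)) + 50
    exons = [(int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_exons)]
    strand = "+" if rng.random() < 0.5 else "-"
    return make_gene(gene_id="R", chrom=chrom, strand=strand, exons_chrom=exons)


def random_read(rng, gene):
    n_blocks = int(rng.integers(1, 4))
    lo = max(0, gene.span.start - 30)
    hi = gene.span.end + 30
    bounds = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_blocks, replace=False))
    blocks = tuple(
        GenomicInterval(gene.chrom, int(bounds[2 * i]), int(bounds[2 * i + 1]) + 1,
                        "+" if rng.random() < 0.5 else "-")
        for i in range(n_blocks)
    )
    strand = blocks[0].strand
    blocks = tuple(GenomicInterval(b.chrom, b.start, b.end, strand) for b in blocks)
    return SplicedRead(read_id="r", chrom=gene.chrom, strand=strand, blocks=blocks)


def test_classify_matches_brute_force_oracle():
    rng = np.random.default_rng(3)
    checked = 0
    for _ in range(150):
        gene = random_gene(rng)
        for _ in range(3):
            read = random_read(rng, gene)
            tol = int(rng.integers(0, 4))
            assert classify_read(read, gene, tol) == brute_force_classify(read, gene, tol)
            checked += 1
    assert checked >= 300


# ------------------------------------------------------------------ parsing


def test_bed12_two_blocks_plus():
    r = parse_bed12_line("c\t0\t400\tr1\t0\t+\t0\t400\t0\t2\t100,100,\t0,300,")
    assert [(b.start, b.end) for b in r.blocks] == [(0, 100), (300, 400)]
    assert r.read_start_5p == 0


def test_bed12_minus_strand_5p_is_rightmost():
    r = parse_bed12_line("c\t0\t400\tr1\t0\t-\t0\t400\t0\t2\t100,100,\t0,300,")
    assert r.read_start_5p == 399


def test_bed12_block_count_mismatch_errors():
    with pytest.raises(ValueError, match="r1"):
        parse_bed12_line("c\t0\t400\tr1\t0\t+\t0\t400\t0\t2\t100,\t0,300,")


def test_load_read_alignments_skips_comments():
    bed = "# comment\nc\t0\t100\tr1\t0\t+\t0\t100\t0\t1\t100,\t0,\n"
    reads = load_read_alignments(io.StringIO(bed))
    assert [r.read_id for r in reads] == ["r1"]


# --------------------------------------------------------------- assignment


def _read(chrom, strand, blocks):
    return SplicedRead("r", chrom, strand, tuple(
        GenomicInterval(chrom, s, e, strand) for s, e in blocks
    ))


def test_assignment_inside_single_gene():
    ann = AnnotationSet([make_gene("A"), make_gene("B", exons_chrom=((800, 1200),))])
    assert assign_read_to_gene(_read("chr1", "+", [(120, 180)]), ann) == "A"


def test_assignment_max_overlap_rule():
    a = make_gene("A", exons_chrom=((0, 1000),))
    b = make_gene("B", exons_chrom=((950, 2000),))
    ann = AnnotationSet([a, b])
    read = _read("chr1", "+", [(100, 960)])  # 860 bp in A, 10 bp in B
    assert assign_read_to_gene(read, ann) == "A"


def test_assignment_below_half_overlap_is_none():
    a = make_gene("A", exons_chrom=((0, 100),))
    ann = AnnotationSet([a])
    read = _read("chr1", "+", [(60, 160)])  # 40 of 100 aligned bp inside
    assert assign_read_to_gene(read, ann) is None


def test_assignment_exact_tie_is_none():
    a = make_gene("A", exons_chrom=((0, 100),))
    b = make_gene("B", exons_chrom=((100, 200),))
    ann = AnnotationSet([a, b])
    read = _read("chr1", "+", [(50, 150)])
    assert assign_read_to_gene(read, ann) is None


# ------------------------------------------------------------ classification


def test_read_at_exon1_start_is_conventional(plus_gene):
    read = _read("chr1", "+", [(100, 200), (300, 400), (500, 650)])
    call = classify_read(read, plus_gene)
    assert call.tss_conventional is True
    assert call.retained_introns == ()
    assert not call.antisense


def test_internal_start_in_intron(plus_gene):
    read = _read("chr1", "+", [(250, 400)])
    call = classify_read(read, plus_gene)
    assert call.tss_conventional is False
    assert call.tss_in_intron is True


def test_one_bp_inside_exon1_is_nonconventional(plus_gene):
    read = _read("chr1", "+", [(101, 200), (300, 400)])
    call = classify_read(read, plus_gene)
    assert call.tss_conventional is False
    assert call.tss_in_intron is False


def test_tss_tolerance_rescues_near_start(plus_gene):
    read = _read("chr1", "+", [(101, 200)])
    assert classify_read(read, plus_gene, tss_tolerance=1).tss_conventional is True


def test_retention_requires_full_containment(plus_gene):
    spanning = _read("chr1", "+", [(100, 450)])  # covers exon1+intron1+exon2
    call = classify_read(spanning, plus_gene)
    assert call.tss_conventional is True
    assert call.retained_introns == (1,)
    partial = _read("chr1", "+", [(100, 250)])  # into intron 1 but not through
    assert classify_read(partial, plus_gene).retained_introns == ()


def test_antisense_has_no_tss_call(plus_gene):
    read = _read("chr1", "-", [(100, 650)])
    call = classify_read(read, plus_gene)
    assert call.antisense and call.tss_conventional is None


def test_wrong_chromosome_errors(plus_gene):
    with pytest.raises(ValueError, match="chr2"):
        classify_read(_read("chr2", "+", [(100, 200)]), plus_gene)


def test_minus_strand_tss_orientation(minus_gene):
    # minus gene: exon 1 is (500,650); conventional start is position 649
    full = _read("chr1", "-", [(100, 649)])
    assert classify_read(full, minus_gene).tss_conventional is False
    at_start = _read("chr1", "-", [(500, 650)])
    assert classify_read(at_start, minus_gene).tss_conventional is True


# -------------------------------------------------------------- aggregation


def _call(gene_id, antisense=False, conv=True, retained=()):
    return ReadCall("r", gene_id, antisense, None if antisense else conv,
                    False, tuple(retained))


def test_metrics_arithmetic(plus_gene):
    calls = [_call("G1", conv=True)] * 8 + [_call("G1", conv=False)] * 2
    calls += [_call("G1", antisense=True)]
    m = gene_longread_metrics(calls, plus_gene, min_reads=5)
    assert m["prop_conventional_tss"] == pytest.approx(0.8)
    assert m["prop_antisense"] == pytest.approx(1 / 11)
    assert m["n_reads_sense"] + m["n_reads_antisense"] == m["n_reads"]
    assert m["n_conventional"] + (m["n_reads_sense"] - m["n_conventional"]) == m["n_reads_sense"]


def test_metrics_undefined_below_min_reads(plus_gene):
    calls = [_call("G1", antisense=True)] * 6
    m = gene_longread_metrics(calls, plus_gene, min_reads=5)
    assert math.isnan(m["prop_conventional_tss"])  # 0 sense reads
    assert m["prop_antisense"] == 1.0


def test_single_exon_gene_retention_undefined():
    gene = make_gene("S", exons_chrom=((0, 500),))
    calls = [_call("S", conv=True)] * 6
    m = gene_longread_metrics(calls, gene, min_reads=5)
    assert math.isnan(m["prop_intron_retained"])
    assert m["prop_conventional_tss"] == 1.0


def test_strand_symmetry_of_classification():
    """Mirroring the coordinate system and flipping strands leaves every
    call (antisense, TSS class, retention count) unchanged."""
    rng = np.random.default_rng(4)
    pivot = 1000
    for _ in range(50):
        gene = random_gene(rng)
        read = random_read(rng, gene)
        call = classify_read(read, gene)
        flip = {"+": "-", "-": "+"}
        m_exons = [(pivot - e.end, pivot - e.start) for e in gene.exons]
        m_gene = make_gene("R", chrom=gene.chrom, strand=flip[gene.strand],
                           exons_chrom=m_exons)
        m_blocks = tuple(
            GenomicInterval(read.chrom, pivot - b.end, pivot - b.start,
                            flip[read.strand])
            for b in reversed(read.blocks)
        )
        m_read = SplicedRead("r", read.chrom, flip[read.strand], m_blocks)
        m_call = classify_read(m_read, m_gene)
        assert m_call.antisense == call.antisense
        assert m_call.tss_conventional == call.tss_conventional
        assert m_call.tss_in_intron == call.tss_in_intron
        assert len(m_call.retained_introns) == len(call.retained_introns)
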