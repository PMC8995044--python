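"""Shared fixtures: small hand-built gene models and one session-scoped
default synthetic bundle that several pipeline-level tests reuse."""

from __future__ import annotations

import dataclasses

import pytest

from gbmti.annotation import AnnotationSet, GeneModel
from gbmti.intervals import GenomicInterval
from gbmti.pipeline import RunConfig, run_longread_analysis
from gbmti.simulate import default_config, planted_truth, simulate_dataset


def make_gene(gene_id="G1", chrom="chr1", strand="+", exons_chrom=((100, 200), (300, 400), (500, 650))):
    """Build a GeneModel from chromosome-ordered exon coordinates."""
    ivs = [GenomicInterval(chrom, s, e, strand) for s, e in sorted(exons_chrom)]
    if strand == "-":
        ivs.reverse()
    span = GenomicInterval(
        chrom, min(i.start for i in ivs), max(i.end for i in ivs), strand
    )
    return GeneModel(gene_id=gene_id, span=span, exons=tuple(ivs))


@pytest.fixture
def plus_gene():
    return make_gene()


@pytest.fixture
def minus_gene():
    return make_gene(gene_id="G2", strand="-")


@pytest.fixture
def annotation(plus_gene, minus_gene):
    shifted = make_gene(
        gene_id="G3", chrom="chr2", exons_chrom=((0, 150), (250, 350))
    )
    return AnnotationSet([plus_gene, minus_gene, shifted])


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """Full default simulation (2000 genes) plus its truth table."""
    outdir = tmp_path_factory.mktemp("bundle") / "default"
    manifest = simulate_dataset(default_config(), seed=20260929, outdir=str(outdir))
    return {
        "dir": str(outdir),
        "manifest": manifest,
        "truth": planted_truth(str(outdir)),
    }


@pytest.fixture(scope="session")
def default_longread_report(default_bundle, tmp_path_factory):
    """Long-read analysis report computed once on the default bundle."""
    d = default_bundle["dir"]
    config = RunConfig(
        annotation=f"{d}/annotation.gff3",
        cytosine_report=f"{d}/cytosine_report.tsv",
        longreads=f"{d}/longreads.bed12",
        outdir=str(tmp_path_factory.mktemp("run")),
    )
    return run_longread_analysis(config)


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down simulation config for fast file-level tests."""
    return dataclasses.replace(default_config(), n_genes=150, shortread_mean_reads_per_gene=60.0)
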