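"""End-to-end analyses: methylation classes x transcript integrity.

Two entry points mirror the two experimental designs:

- :func:`run_longread_analysis` — classify genes from a bisulfite cytosine
  report, classify full-length long reads, and compare gbM vs UM genes on
  conventional-TSS, antisense and intron-retention proportions (two-sided
  Wilcoxon plus the covariate-adjusted proportion GLM).
- :func:`run_shortread_analysis` — compute exon3/exon1 and intron-RPKM
  coverage metrics per condition (e.g. WT and a methylation mutant) and
  compare gbM vs UM within each condition with one-sided Wilcoxon tests.
  Methylation labels always come from the designated reference (WT)
  methylome and are propagated to every condition, so a group difference
  that persists in a mutant lacking gbM flags a gene property rather than
  a methylation effect.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import __version__
from .annotation import AnnotationSet, load_annotation
from .longread import call_reads, load_read_alignments, longread_metrics_table, read_calls_table
from .methylation import (
    call_site_methylation,
    classify_genes,
    compute_background,
    profile_genes,
    read_cytosine_report,
    summarize_classification,
)
from .shortread import load_short_reads, shortread_metrics_table
from .stats import ComparisonResult, compare_groups

logger = logging.getLogger(__name__)

LONGREAD_METRICS = ("prop_conventional_tss", "prop_antisense", "prop_intron_retained")


@dataclass
class RunConfig:
    """Paths and thresholds for one analysis run."""

    annotation: str
    cytosine_report: str
    longreads: Optional[str] = None
    shortreads: dict[str, str] = field(default_factory=dict)  # condition -> BED
    shortread_library_sizes: dict[str, int] = field(default_factory=dict)
    outdir: str = "gbmti_run"
    alpha: float = 0.05
    min_coverage: int = 3
    min_sites: int = 20
    min_reads: int = 5
    tss_tolerance: int = 0
    min_denominator: int = 1
    strandedness: str = "unstranded"
    error_rate: float = 0.005
    strict_gbm: bool = False
    seed: Optional[int] = None

    def validate(self) -> None:
        for path in [self.annotation, self.cytosine_report, self.longreads, *self.shortreads.values()]:
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(path)
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0,1)")


@dataclass
class AnalysisReport:
    comparisons: list[ComparisonResult]
    gene_table: pd.DataFrame
    provenance: dict

    def comparison_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.comparisons])

    def write(self, outdir: str, prefix: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.gene_table.to_csv(
            os.path.join(outdir, f"{prefix}_gene_table.tsv"), sep="\t", index=False
        )
        self.comparison_frame().to_csv(
            os.path.join(outdir, f"{prefix}_comparisons.tsv"), sep="\t", index=False
        )
        payload = {
            "provenance": self.provenance,
            "comparisons": [c.to_dict() for c in self.comparisons],
        }
        with open(os.path.join(outdir, f"{prefix}_report.json"), "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _provenance(config: RunConfig, inputs: list[str]) -> dict:
    return {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input_checksums": {p: _checksum(p) for p in inputs if p},
        # denominator definitions for every reported comparison
        "denominators": {
            "prop_conventional_tss": "conventional sense reads / sense reads",
            "prop_antisense": "antisense reads / all assigned reads",
            "prop_intron_retained": "sense reads retaining >=1 intron / sense reads",
            "exon3_exon1_ratio": "reads on exon 3 / reads on exon 1",
            "intron_rpkm": "intron reads * 1e9 / (library size * pooled intron bp)",
        },
        "glm_sign_convention": "contrast = UM minus gbM on the logit scale",
    }


def classify_methylation(config: RunConfig, annotation: AnnotationSet) -> tuple[pd.DataFrame, dict]:
    """Cytosine report -> per-gene class labels (plus JSON-able summary)."""
    sites = read_cytosine_report(config.cytosine_report, min_coverage=config.min_coverage)
    called = call_site_methylation(sites, error_rate=config.error_rate, alpha=config.alpha)
    profiles = profile_genes(sites, annotation, called)
    background = compute_background(profiles)
    classes = classify_genes(
        profiles,
        background,
        alpha=config.alpha,
        min_sites=config.min_sites,
        strict=config.strict_gbm,
    )
    return classes, summarize_classification(classes, background)


def _check_two_classes(labels: pd.Series) -> None:
    for lbl in ("gbM", "UM"):
        if (labels == lbl).sum() == 0:
            raise ValueError(
                f"zero genes labeled {lbl} after classification filtering "
                f"(alpha/min_sites); cannot run gbM-vs-UM comparison"
            )


def run_longread_analysis(config: RunConfig) -> AnalysisReport:
    """Long-read analysis: classify genes and reads, compare gbM vs UM."""
    config.validate()
    if config.longreads is None:
        raise ValueError("config.longreads is required")
    annotation = load_annotation(config.annotation)
    classes, summary = classify_methylation(config, annotation)
    _check_two_classes(classes["class_label"])
    reads = load_read_alignments(config.longreads)
    calls = call_reads(reads, annotation, tss_tolerance=config.tss_tolerance)
    metrics = longread_metrics_table(calls, annotation, min_reads=config.min_reads)
    table = metrics.merge(classes[["gene_id", "class_label"]], on="gene_id")
    comparisons = []
    fav_cols = {
        "prop_conventional_tss": ("n_conventional", "n_reads_sense"),
        "prop_antisense": ("n_reads_antisense", "n_reads"),
        "prop_intron_retained": ("n_retaining", "n_reads_sense"),
    }
    for metric in LONGREAD_METRICS:
        fav, elig = fav_cols[metric]
        comparisons.append(
            compare_groups(
                table, metric, alternative="two-sided", glm=True,
                favorable_col=fav, eligible_col=elig,
            )
        )
    prov = _provenance(config, [config.annotation, config.cytosine_report, config.longreads])
    prov["classification_summary"] = summary
    report = AnalysisReport(comparisons=comparisons, gene_table=table, provenance=prov)
    os.makedirs(config.outdir, exist_ok=True)
    read_calls_table(calls).to_csv(
        os.path.join(config.outdir, "read_calls.tsv"), sep="\t", index=False
    )
    classes.to_csv(os.path.join(config.outdir, "gene_classes.tsv"), sep="\t", index=False)
    report.write(config.outdir, "longread")
    return report


def run_shortread_analysis(config: RunConfig) -> AnalysisReport:
    """Short-read analysis across conditions, labels fixed from the
    reference methylome."""
    config.validate()
    if not config.shortreads:
        raise ValueError("config.shortreads must name >=1 condition")
    annotation = load_annotation(config.annotation)
    classes, summary = classify_methylation(config, annotation)
    _check_two_classes(classes["class_label"])
    labels = classes[["gene_id", "class_label"]]
    comparisons = []
    tables = []
    for cond in sorted(config.shortreads):
        reads = load_short_reads(config.shortreads[cond])
        library_size = config.shortread_library_sizes.get(cond, len(reads))
        if len(reads) > library_size:
            raise ValueError(
                f"condition {cond}: read file has {len(reads)} reads but "
                f"library_size={library_size}"
            )
        metrics = shortread_metrics_table(
            reads, annotation, library_size,
            strandedness=config.strandedness,
            min_denominator=config.min_denominator,
        )
        table = metrics.merge(labels, on="gene_id")
        table.insert(0, "condition", cond)
        tables.append(table)
        for metric in ("exon3_exon1_ratio", "intron_rpkm"):
            cmp = compare_groups(table, metric, alternative="a_less")
            cmp.metric = f"{cond}:{metric}"
            comparisons.append(cmp)
    gene_table = pd.concat(tables, ignore_index=True)
    prov = _provenance(
        config,
        [config.annotation, config.cytosine_report, *config.shortreads.values()],
    )
    prov["classification_summary"] = summary
    prov["label_source"] = "reference methylome (labels propagated to all conditions)"
    report = AnalysisReport(comparisons=comparisons, gene_table=gene_table, provenance=prov)
    os.makedirs(config.outdir, exist_ok=True)
    classes.to_csv(os.path.join(config.outdir, "gene_classes.tsv"), sep="\t", index=False)
    report.write(config.outdir, "shortread")
    return report
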