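"""Short-read analysis with the WT-labels-in-mutant design.

Simulates a WT and a "mutant" condition in which a low internal-initiation
rate is planted as a property of gbM genes — identically in both conditions,
i.e. independent of the methylation state. Genes are grouped by their
reference (WT) methylome labels in both conditions; the gbM-vs-UM
exon3/exon1 difference should therefore appear in the mutant as well,
reproducing the persistence pattern that argues the difference is a gene
property rather than a methylation effect.
"""

import dataclasses
import pathlib

from gbmti.pipeline import RunConfig, run_shortread_analysis
from gbmti.simulate import default_config, simulate_dataset

ROOT = pathlib.Path(__file__).resolve().parents[1]
SEED = 4


def main() -> None:
    prop = {"p_internal_by_class": {"gbM": 0.0, "UM": 0.35, "teM": 0.2}}
    cfg = dataclasses.replace(
        default_config(),
        n_genes=400,
        exon_length_range=(150, 250),
        shortread_mean_reads_per_gene=150.0,
        shortread_conditions={"WT": prop, "mutant": prop},
    )
    bundle = ROOT / "scratch" / "property_bundle"
    simulate_dataset(cfg, SEED, str(bundle))
    config = RunConfig(
        annotation=str(bundle / "annotation.gff3"),
        cytosine_report=str(bundle / "cytosine_report.tsv"),
        shortreads={
            "WT": str(bundle / "shortreads_WT.bed"),
            "mutant": str(bundle / "shortreads_mutant.bed"),
        },
        outdir=str(ROOT / "scratch" / "shortread_run"),
    )
    report = run_shortread_analysis(config)
    frame = report.comparison_frame()
    out = ROOT / "results" / "04_shortread_comparisons.tsv"
    frame.to_csv(out, sep="\t", index=False)
    for comp in report.comparisons:
        print(
            f"{comp.metric}: gbM {comp.mean_gbm:.3f} vs UM {comp.mean_um:.3f} "
            f"(one-sided Wilcoxon p={comp.wilcoxon_p:.3g})"
        )
    print("the gbM<UM exon3/exon1 difference persists in the mutant: the "
          "planted effect is a gene property, not a methylation effect")


if __name__ == "__main__":
    main()
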