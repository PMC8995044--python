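"""Classify every simulated gene as gbM / UM / teM / undetermined from the
bisulfite cytosine report and check the calls against the planted truth.

Reads the bundle from scratch/bundle (run 01_simulate.py first); writes the
per-gene classification to scratch/ and a summary with the recovery rate to
results/.
"""

import json
import pathlib

from gbmti.annotation import load_annotation
from gbmti.pipeline import RunConfig, classify_methylation
from gbmti.simulate import planted_truth

ROOT = pathlib.Path(__file__).resolve().parents[1]
BUNDLE = ROOT / "scratch" / "bundle"


def main() -> None:
    config = RunConfig(
        annotation=str(BUNDLE / "annotation.gff3"),
        cytosine_report=str(BUNDLE / "cytosine_report.tsv"),
    )
    annotation = load_annotation(config.annotation)
    classes, summary = classify_methylation(config, annotation)
    classes.to_csv(ROOT / "scratch" / "gene_classes.tsv", sep="\t", index=False)

    truth = planted_truth(str(BUNDLE))
    merged = classes.merge(
        truth[["gene_id", "class_label"]], on="gene_id",
        suffixes=("_called", "_planted"),
    )
    eligible = merged[merged["n_sites_CG"] >= config.min_sites]
    recovery = float(
        (eligible["class_label_called"] == eligible["class_label_planted"]).mean()
    )
    summary["planted_label_recovery"] = recovery
    summary["n_eligible"] = int(len(eligible))
    out = ROOT / "results" / "02_classification_summary.json"
    out.write_text(json.dumps(summary, indent=2) + "\n")
    print(f"labels: {summary['label_counts']}; background CG rate "
          f"{summary['background_rates']['CG']:.3f}; recovered the planted "
          f"label for {100 * recovery:.2f}% of {len(eligible)} eligible genes")


if __name__ == "__main__":
    main()
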