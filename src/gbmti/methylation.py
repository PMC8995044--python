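"""Gene methylation classification from per-cytosine bisulfite counts.

Genes are labeled ``gbM`` (gene-body methylated: CG methylation
significantly above the genic average, CHG/CHH not elevated), ``UM``
(unmethylated: CG significantly below the genic average and nothing
elevated), ``teM`` (TE-like: CHG or CHH elevated), or ``undetermined``.

The procedure is two-stage. Stage one calls each covered cytosine site
methylated or not with an exact upper-tail binomial test against the
bisulfite non-conversion error rate, FDR-adjusted across all sites. Stage
two compares each gene's count of methylated sites per context against the
pooled genic-average rate with exact binomial tail tests, FDR-adjusted
across genes within each context/tail family (Benjamini-Hochberg).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import AnnotationSet

CONTEXTS = ("CG", "CHG", "CHH")

#: column order of a Bismark-style cytosine report
REPORT_COLUMNS = ("chrom", "pos", "strand", "meth_reads", "unmeth_reads", "context", "tri")


@dataclass(frozen=True)
class BackgroundRates:
    """Pooled genic-average fraction of methylated sites, per context."""

    p_bg: dict[str, float]

    def __post_init__(self) -> None:
        for c, p in self.p_bg.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"background rate for {c} outside [0,1]: {p}")


def read_cytosine_report(source: str | IO[str], min_coverage: int = 3) -> pd.DataFrame:
    """Read a Bismark-style cytosine report into a site table.

    Input columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context, trinucleotide. Sites with coverage below
    ``min_coverage`` are dropped; positions become 0-based.
    """
    df = pd.read_csv(
        source,
        sep="\t",
        header=None,
        names=list(REPORT_COLUMNS),
        dtype={"chrom": str, "strand": str, "context": str, "tri": str},
    )
    for col in ("pos", "meth_reads", "unmeth_reads"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or not np.allclose(vals, vals.astype(np.int64)):
            raise ValueError(f"non-integer values in column {col!r}")
        df[col] = vals.astype(np.int64)
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(f"unknown methylation context {df.loc[bad, 'context'].iloc[0]!r}")
    df["pos"] = df["pos"] - 1
    cov = df["meth_reads"] + df["unmeth_reads"]
    return df.loc[cov >= min_coverage].reset_index(drop=True)


def site_upper_pvalue(meth, total, error_rate: float = 0.005):
    """Exact binomial upper-tail P(X >= meth | total, error_rate)."""
    meth = np.asarray(meth)
    total = np.asarray(total)
    if np.any(total <= 0):
        raise ValueError("site with zero total reads")
    return stats.binom.sf(meth - 1, total, error_rate)


def call_site_methylation(
    sites: pd.DataFrame, error_rate: float = 0.005, alpha: float = 0.05
) -> pd.Series:
    """Call each site methylated/unmethylated.

    A site is methylated iff its exact binomial upper-tail p-value against
    the non-conversion error rate is significant after BH adjustment across
    all sites in the table.
    """
    if not 0.0 < error_rate < 1.0:
        raise ValueError(f"error_rate outside (0,1): {error_rate}")
    total = (sites["meth_reads"] + sites["unmeth_reads"]).to_numpy()
    p = site_upper_pvalue(sites["meth_reads"].to_numpy(), total, error_rate)
    called, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return pd.Series(called, index=sites.index, name="methylated")


def profile_genes(
    sites: pd.DataFrame, annotation: AnnotationSet, methylated: pd.Series
) -> pd.DataFrame:
    """Aggregate site calls per gene and context.

    A site contributes to every gene whose span contains it (either strand:
    gene-body methylation pools both strands). Returns one row per gene with
    ``n_sites_<ctx>`` and ``n_meth_<ctx>`` columns; genes without covered
    sites get zero rows of counts.
    """
    cols = {f"n_sites_{c}": 0 for c in CONTEXTS} | {f"n_meth_{c}": 0 for c in CONTEXTS}
    out = pd.DataFrame(cols, index=pd.Index(sorted(annotation.genes), name="gene_id"))
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()
    ctx_arr = sites["context"].to_numpy()
    meth_arr = methylated.to_numpy()
    for chrom in np.unique(chrom_arr):
        mask = chrom_arr == chrom
        genes = [g for g in annotation if g.chrom == chrom]
        if not genes:
            continue
        pos_c = pos_arr[mask]
        ctx_c = ctx_arr[mask]
        meth_c = meth_arr[mask]
        order = np.argsort(pos_c, kind="stable")
        pos_c, ctx_c, meth_c = pos_c[order], ctx_c[order], meth_c[order]
        for g in genes:
            lo = np.searchsorted(pos_c, g.span.start, side="left")
            hi = np.searchsorted(pos_c, g.span.end - 1, side="right")
            if lo == hi:
                continue
            sl = slice(lo, hi)
            for c in CONTEXTS:
                in_ctx = ctx_c[sl] == c
                out.at[g.gene_id, f"n_sites_{c}"] = int(in_ctx.sum())
                out.at[g.gene_id, f"n_meth_{c}"] = int((in_ctx & meth_c[sl]).sum())
    return out.reset_index()


def compute_background(profiles: pd.DataFrame) -> BackgroundRates:
    """Pooled genic-average methylated-site fraction per context."""
    rates = {}
    for c in CONTEXTS:
        n = profiles[f"n_sites_{c}"].sum()
        if n == 0:
            raise ValueError(f"no covered sites genome-wide in context {c}")
        rates[c] = float(profiles[f"n_meth_{c}"].sum() / n)
    return BackgroundRates(rates)


def classify_genes(
    profiles: pd.DataFrame,
    background: BackgroundRates,
    alpha: float = 0.05,
    min_sites: int = 20,
    strict: bool = False,
) -> pd.DataFrame:
    """Label every gene gbM / UM / teM / undetermined.

    Per context, exact binomial upper- and lower-tail p-values of the
    methylated-site count against the genic average are BH-adjusted across
    genes (one family per context and tail). Labels:

    - ``teM``: CHG or CHH upper tail significant (trumps gbM);
    - ``gbM``: CG upper tail significant and no non-CG elevation; with
      ``strict=True`` additionally CHG and CHH lower tails significant;
    - ``UM``: no upper tail significant anywhere and CG lower tail
      significant;
    - ``undetermined`` otherwise, or when the gene has fewer than
      ``min_sites`` covered CG sites (reason recorded, no exception).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha outside (0,1): {alpha}")
    out = profiles.copy()
    up_sig: dict[str, np.ndarray] = {}
    low_sig: dict[str, np.ndarray] = {}
    for c in CONTEXTS:
        n = out[f"n_sites_{c}"].to_numpy()
        k = out[f"n_meth_{c}"].to_numpy()
        p = background.p_bg[c]
        covered = n > 0
        p_up = np.ones(len(out))
        p_low = np.ones(len(out))
        p_up[covered] = stats.binom.sf(k[covered] - 1, n[covered], p)
        p_low[covered] = stats.binom.cdf(k[covered], n[covered], p)
        q_up = np.ones(len(out))
        q_low = np.ones(len(out))
        if covered.any():
            q_up[covered] = multipletests(p_up[covered], method="fdr_bh")[1]
            q_low[covered] = multipletests(p_low[covered], method="fdr_bh")[1]
        out[f"q_up_{c}"] = q_up
        out[f"q_low_{c}"] = q_low
        up_sig[c] = covered & (q_up < alpha)
        low_sig[c] = covered & (q_low < alpha)

    eligible = out["n_sites_CG"].to_numpy() >= min_sites
    is_tem = up_sig["CHG"] | up_sig["CHH"]
    is_gbm = up_sig["CG"] & ~is_tem
    if strict:
        is_gbm &= low_sig["CHG"] & low_sig["CHH"]
    no_up = ~(up_sig["CG"] | is_tem)
    is_um = no_up & low_sig["CG"]

    label = np.full(len(out), "undetermined", dtype=object)
    reason = np.full(len(out), "", dtype=object)
    label[is_um] = "UM"
    label[is_gbm] = "gbM"
    label[is_tem] = "teM"
    label[~eligible] = "undetermined"
    reason[~eligible] = "insufficient_CG_sites"
    out["class_label"] = label
    out["reason"] = reason
    return out


def write_classification(classes: pd.DataFrame, path: str) -> None:
    classes.to_csv(path, sep="\t", index=False)


def summarize_classification(classes: pd.DataFrame, background: BackgroundRates) -> dict:
    counts = classes["class_label"].value_counts().to_dict()
    return {
        "background_rates": {c: background.p_bg[c] for c in CONTEXTS},
        "label_counts": {k: int(v) for k, v in counts.items()},
        "n_genes": int(len(classes)),
    }


def write_summary(summary: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2)
        fh.write("\n")
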