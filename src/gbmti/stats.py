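"""Group comparisons between gbM and UM genes.

Two complementary routes:

- **Wilcoxon rank-sum** (Mann-Whitney U) on any per-gene metric, one- or
  two-sided. Exact enumeration for small tie-free samples, tie-corrected
  normal approximation otherwise.
- **Covariate-adjusted proportion GLM** for metrics that are per-gene
  proportions with denominators (conventional-TSS, antisense, intron
  retention): binomial family with logit link, linear predictor
  ``class + log10(length) + log10(1 + expression)``, quasi-likelihood
  dispersion so standard errors are robust to between-gene overdispersion.
  The class contrast is reported as UM minus gbM on the link (logit) scale:
  positive means the UM group is higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

_ALTERNATIVES = {"two-sided": "two-sided", "a_less": "less", "a_greater": "greater"}

EXACT_LIMIT = 8


@dataclass
class GlmFit:
    """Fitted proportion GLM with named coefficients (logit scale)."""

    params: pd.Series
    bse: pd.Series
    scale: float
    n_obs: int
    converged: bool
    separation_warning: bool = False


@dataclass
class ComparisonResult:
    """Group-difference report for one metric."""

    metric: str
    mean_gbm: float
    mean_um: float
    n_gbm: int
    n_um: int
    wilcoxon_statistic: float
    wilcoxon_alternative: str
    wilcoxon_p: float
    glm: Optional[dict] = field(default=None)

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric,
            "mean_gbM": self.mean_gbm,
            "mean_UM": self.mean_um,
            "n_gbM": self.n_gbm,
            "n_UM": self.n_um,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_alternative": self.wilcoxon_alternative,
            "wilcoxon_p": self.wilcoxon_p,
        }
        if self.glm is not None:
            d.update({f"glm_{k}": v for k, v in self.glm.items()})
        return d


def wilcoxon_rank_sum(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test of two samples.

    ``alternative`` is one of ``two-sided``, ``a_less`` (first sample
    stochastically smaller) or ``a_greater``. Uses exact enumeration when
    both samples are tie-free and min(n) <= 8, otherwise the tie-corrected
    normal approximation. Returns (U statistic of sample a, p-value).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"unknown alternative {alternative!r}")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and min(a.size, b.size) <= EXACT_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=_ALTERNATIVES[alternative], method=method)
    return float(res.statistic), float(res.pvalue)


def _design_matrix(table: pd.DataFrame, with_covariates: bool) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["intercept"] = 1.0
    X["class_UM"] = (table["class_label"] == "UM").astype(float)
    if with_covariates:
        X["log10_length"] = np.log10(table["gene_length"].astype(float))
        X["log10_expression"] = np.log10(1.0 + table["expression_proxy"].astype(float))
    return X


def fit_proportion_glm(table: pd.DataFrame, with_covariates: bool = True) -> GlmFit:
    """Fit the covariate-adjusted binomial GLM to per-gene counts.

    ``table`` needs columns ``class_label`` (gbM/UM), ``favorable_count``,
    ``eligible_count``, ``gene_length`` and ``expression_proxy``. Rows with
    zero eligible reads are dropped. The dispersion parameter is estimated
    from the Pearson chi-square (quasi-likelihood), inflating standard
    errors under overdispersion.
    """
    table = table.loc[table["eligible_count"] > 0].copy()
    counts = table["class_label"].value_counts()
    for lbl in ("gbM", "UM"):
        if counts.get(lbl, 0) < 2:
            raise ValueError(f"need >=2 genes in class {lbl}, got {counts.get(lbl, 0)}")
    fav = table["favorable_count"].to_numpy(dtype=float)
    elig = table["eligible_count"].to_numpy(dtype=float)
    if np.any(fav > elig) or np.any(fav < 0):
        raise ValueError("favorable_count must lie in [0, eligible_count]")
    X = _design_matrix(table, with_covariates)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix")
    endog = np.column_stack([fav, elig - fav])
    model = sm.GLM(endog, X, family=sm.families.Binomial())
    res = model.fit()
    # quasi-binomial dispersion (Pearson chi2 / df), as in R's quasibinomial:
    # SEs are inflated by sqrt(scale) when the per-gene counts are
    # overdispersed relative to the binomial
    scale = float(res.pearson_chi2 / res.df_resid) if res.df_resid > 0 else 1.0
    bse = res.bse * np.sqrt(scale)
    separation = bool(np.any(np.abs(res.params) > 20) or np.any(~np.isfinite(bse)))
    return GlmFit(
        params=pd.Series(res.params, index=X.columns),
        bse=pd.Series(bse, index=X.columns),
        scale=scale,
        n_obs=int(len(table)),
        converged=bool(getattr(res, "converged", True)),
        separation_warning=separation,
    )


def class_contrast(fit: GlmFit) -> dict:
    """UM-minus-gbM contrast on the logit scale, with Wald Z and p."""
    est = float(fit.params["class_UM"])
    se = float(fit.bse["class_UM"])
    z = est / se if se > 0 else float("inf") * np.sign(est)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {
        "contrast_estimate": est,
        "SE": se,
        "z_ratio": float(z),
        "p": p,
        "covariates": {
            k: float(fit.params[k])
            for k in ("log10_length", "log10_expression")
            if k in fit.params.index
        },
        "separation_warning": fit.separation_warning,
    }


def compare_groups(
    table: pd.DataFrame,
    metric: str,
    alternative: str = "two-sided",
    glm: bool = False,
    favorable_col: Optional[str] = None,
    eligible_col: Optional[str] = None,
) -> ComparisonResult:
    """Compare gbM vs UM genes on one per-gene metric.

    ``table`` needs ``class_label`` and the metric column; rows whose metric
    is NaN are excluded. When ``glm=True`` the proportion GLM is fitted from
    ``favorable_col`` / ``eligible_col`` counts in addition to the Wilcoxon
    test (continuous metrics use the Wilcoxon route only).
    """
    sub = table.loc[table["class_label"].isin(["gbM", "UM"]) & table[metric].notna()]
    a = sub.loc[sub["class_label"] == "gbM", metric].to_numpy(dtype=float)
    b = sub.loc[sub["class_label"] == "UM", metric].to_numpy(dtype=float)
    stat, p = wilcoxon_rank_sum(a, b, alternative)
    glm_report = None
    if glm:
        if favorable_col is None or eligible_col is None:
            raise ValueError("glm=True needs favorable_col and eligible_col")
        fit_table = sub.rename(
            columns={favorable_col: "favorable_count", eligible_col: "eligible_count"}
        )
        glm_report = class_contrast(fit_proportion_glm(fit_table))
    return ComparisonResult(
        metric=metric,
        mean_gbm=float(a.mean()),
        mean_um=float(b.mean()),
        n_gbm=int(a.size),
        n_um=int(b.size),
        wilcoxon_statistic=stat,
        wilcoxon_alternative=alternative,
        wilcoxon_p=p,
        glm=glm_report,
    )
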