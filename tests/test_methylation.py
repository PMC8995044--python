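"""Methylation classification: site calls, backgrounds, gene labels."""

import io
import math

import numpy as np
import pandas as pd
import pytest

from gbmti.methylation import (
    BackgroundRates,
    call_site_methylation,
    classify_genes,
    compute_background,
    read_cytosine_report,
    site_upper_pvalue,
)

# ------------------------------------------------------------------ oracles


def binom_upper_tail(k: int, n: int, p: float) -> float:
    """Independent exact oracle: direct pmf summation."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def binom_lower_tail(k: int, n: int, p: float) -> float:
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(0, k + 1)
    )


def bh_adjust(pvals):
    """Plain Benjamini-Hochberg, written independently for cross-checks."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


# ----------------------------------------------------------- report parsing


def _report(text: str) -> io.StringIO:
    return io.StringIO(text.replace(" ", "\t"))


def test_report_parsing_converts_to_zero_based():
    df = read_cytosine_report(_report("Chr1 100 + 5 0 CG CGA\n"), min_coverage=3)
    row = df.iloc[0]
    assert (row["chrom"], row["pos"], row["strand"]) == ("Chr1", 99, "+")
    assert (row["meth_reads"], row["unmeth_reads"], row["context"]) == (5, 0, "CG")


def test_report_coverage_filter():
    df = read_cytosine_report(
        _report("Chr1 10 + 1 1 CG CGA\nChr1 20 + 2 1 CG CGA\n"), min_coverage=3
    )
    assert list(df["pos"]) == [19]


def test_report_unknown_context_errors():
    with pytest.raises(ValueError, match="context"):
        read_cytosine_report(_report("Chr1 10 + 3 0 CNN CNN\n"))


def test_report_non_integer_counts_error():
    with pytest.raises(ValueError, match="non-integer"):
        read_cytosine_report(_report("Chr1 10 + 2.5 0 CG CGA\n"))


# ------------------------------------------------------------- site calling


def test_site_upper_pvalue_matches_exact_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(1, 60))
        k = int(rng.integers(0, n + 1))
        p = float(rng.uniform(0.001, 0.5))
        assert site_upper_pvalue(k, n, p) == pytest.approx(
            binom_upper_tail(k, n, p), rel=1e-9, abs=1e-300
        )


def test_fully_methylated_site_called():
    sites = pd.DataFrame({"meth_reads": [5, 0], "unmeth_reads": [0, 10]})
    called = call_site_methylation(sites, error_rate=0.005)
    assert list(called) == [True, False]
    # upper-tail p for 5/5 at p=0.005 is 0.005^5
    assert site_upper_pvalue(5, 5, 0.005) == pytest.approx(0.005**5, rel=1e-12)


def test_site_calls_match_oracle_fdr():
    """Calls equal exact-binomial p-values + independent BH at alpha."""
    rng = np.random.default_rng(1)
    n = rng.integers(3, 20, size=300)
    k = rng.binomial(n, np.where(rng.random(300) < 0.2, 0.8, 0.005))
    sites = pd.DataFrame({"meth_reads": k, "unmeth_reads": n - k})
    called = call_site_methylation(sites, error_rate=0.005, alpha=0.05)
    pvals = [binom_upper_tail(int(ki), int(ni), 0.005) for ki, ni in zip(k, n)]
    expected = bh_adjust(pvals) < 0.05
    assert list(called) == list(expected)


def test_zero_coverage_site_errors():
    sites = pd.DataFrame({"meth_reads": [0], "unmeth_reads": [0]})
    with pytest.raises(ValueError, match="zero total"):
        call_site_methylation(sites)


# ---------------------------------------------------------------- background


def _profiles(rows):
    cols = ["gene_id"]
    for c in ("CG", "CHG", "CHH"):
        cols += [f"n_sites_{c}", f"n_meth_{c}"]
    return pd.DataFrame(rows, columns=cols)


def test_background_pools_over_genes():
    prof = _profiles(
        [["g1", 100, 10, 50, 0, 80, 0], ["g2", 100, 30, 50, 0, 80, 0]]
    )
    bg = compute_background(prof)
    assert bg.p_bg["CG"] == pytest.approx(40 / 200)


def test_background_zero_sites_names_context():
    prof = _profiles([["g1", 100, 10, 0, 0, 80, 0]])
    with pytest.raises(ValueError, match="CHG"):
        compute_background(prof)


def test_saturated_background_never_significant():
    prof = _profiles([["g1", 100, 50, 50, 0, 80, 80], ["g2", 100, 50, 50, 0, 80, 80]])
    bg = compute_background(prof)
    assert bg.p_bg["CHH"] == 1.0
    out = classify_genes(prof, bg)
    assert not (out["q_up_CHH"] < 0.05).any()


def test_background_rates_validated():
    with pytest.raises(ValueError):
        BackgroundRates({"CG": 1.5, "CHG": 0.0, "CHH": 0.0})


# ------------------------------------------------------------ classification

BG = BackgroundRates({"CG": 0.05, "CHG": 0.03, "CHH": 0.02})


def test_classify_three_archetypes():
    """gbM, UM and teM archetypes from exact binomial tails (teM trumps a
    significant CG elevation)."""
    prof = _profiles(
        [
            ["gbm", 100, 30, 50, 0, 80, 0],
            ["um", 100, 0, 50, 0, 80, 0],
            ["tem", 100, 40, 50, 25, 80, 30],
        ]
    )
    out = classify_genes(prof, BG, alpha=0.05, min_sites=20)
    labels = dict(zip(out["gene_id"], out["class_label"]))
    assert labels == {"gbm": "gbM", "um": "UM", "tem": "teM"}
    # the driving tails match the independent oracle (before BH, p <= q)
    assert binom_upper_tail(30, 100, 0.05) < 1e-13
    assert binom_lower_tail(0, 100, 0.05) == pytest.approx(0.95**100, rel=1e-12)
    assert binom_upper_tail(25, 50, 0.03) < 1e-20


def test_gene_tails_match_oracle_values():
    prof = _profiles([["g", 100, 30, 50, 0, 80, 0], ["h", 100, 5, 50, 1, 80, 1]])
    out = classify_genes(prof, BG).set_index("gene_id")
    # two genes per family: BH keeps the smaller p as p*2/1 capped by the larger
    p_up = [binom_upper_tail(30, 100, 0.05), binom_upper_tail(5, 100, 0.05)]
    expected = bh_adjust(p_up)
    assert out.loc["g", "q_up_CG"] == pytest.approx(expected[0], rel=1e-9)
    assert out.loc["h", "q_up_CG"] == pytest.approx(expected[1], rel=1e-9)


def test_insufficient_cg_sites_undetermined_with_reason():
    prof = _profiles([["tiny", 10, 9, 50, 0, 80, 0], ["big", 100, 50, 50, 0, 80, 0]])
    out = classify_genes(prof, BG, min_sites=20).set_index("gene_id")
    assert out.loc["tiny", "class_label"] == "undetermined"
    assert out.loc["tiny", "reason"] == "insufficient_CG_sites"
    assert out.loc["big", "class_label"] == "gbM"


def test_every_gene_gets_exactly_one_label():
    rng = np.random.default_rng(2)
    n = 300
    prof = _profiles(
        [
            [f"g{i}", 50, int(rng.integers(0, 51)), 40, int(rng.integers(0, 41)),
             60, int(rng.integers(0, 61))]
            for i in range(n)
        ]
    )
    bg = compute_background(prof)
    out = classify_genes(prof, bg)
    assert len(out) == n
    assert out["class_label"].isin(["gbM", "UM", "teM", "undetermined"]).all()


def test_monotonicity_in_cg_methylation():
    """With everything else fixed, more CG methylation never turns gbM into
    UM (labels walk UM -> undetermined -> gbM)."""
    order = {"UM": 0, "undetermined": 1, "gbM": 2, "teM": 2}
    prev = -1
    for k in range(0, 101, 5):
        prof = _profiles(
            [["g", 100, k, 50, 0, 80, 0], ["anchor", 100, 5, 50, 2, 80, 2]]
        )
        out = classify_genes(prof, BG).set_index("gene_id")
        rank = order[out.loc["g", "class_label"]]
        assert rank >= prev
        prev = rank


def test_strict_mode_requires_low_non_cg():
    # CHG/CHH lower tails are not significant here (few sites), so strict
    # mode demotes the gene to undetermined
    prof = _profiles([["g", 100, 30, 3, 0, 3, 0], ["h", 100, 2, 3, 0, 3, 0]])
    lax = classify_genes(prof, BG, strict=False).set_index("gene_id")
    strict = classify_genes(prof, BG, strict=True).set_index("gene_id")
    assert lax.loc["g", "class_label"] == "gbM"
    assert strict.loc["g", "class_label"] == "undetermined"
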