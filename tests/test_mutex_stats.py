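"""Exact-test oracles, odds-ratio arithmetic and the stratified screen."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mutexome import (
    SynthConfig,
    build_contingency,
    compare_vaf,
    dual_mutant_enrichment,
    fisher_exact_2x2,
    gen_genotypes,
    odds_ratio_ci,
    size_significance_correlation,
    stratified_screen,
    evaluate_contingency,
)
from mutexome.mutex_stats import ContingencyResult


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Exhaustive enumeration over the fixed-margins family (independent path)."""
    n = a + b + c + d
    r1, c1 = a + c, a + b  # ESR1-WT and TP53-WT margins
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        return 1.0
    denom = comb(n, c1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom for x in range(lo, hi + 1)}
    cutoff = probs[a] * (1 + 1e-7)
    return min(1.0, sum(p for p in probs.values() if p <= cutoff))


def test_fisher_worked_examples():
    # exhaustive enumeration over a in {0,1,2}: probs 1/6, 4/6, 1/6
    assert fisher_exact_2x2(2, 0, 0, 2) == pytest.approx(1 / 3)
    # symmetric table is the mode of its distribution
    assert fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)
    # zero margin -> degenerate, p = 1 by convention
    assert fisher_exact_2x2(0, 0, 3, 5) == 1.0


def test_fisher_matches_enumeration_oracle_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(300):
        n = int(rng.integers(1, 31))
        cuts = np.sort(rng.integers(0, n + 1, size=3))
        a, b, c, d = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1], n - cuts[2]
        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-10
        )


def test_fisher_agrees_with_independent_library():
    # scipy's implementation is the cross-check, never the implementation path
    rng = np.random.default_rng(1)
    for _ in range(100):
        t = rng.integers(0, 15, size=4)
        if (t[0] + t[2]) in (0, t.sum()) or (t[0] + t[1]) in (0, t.sum()):
            continue
        ours = fisher_exact_2x2(*t)
        theirs = stats.fisher_exact([[t[0], t[2]], [t[1], t[3]]]).pvalue
        assert ours == pytest.approx(theirs, rel=1e-9)


def test_odds_ratio_worked_examples():
    or_est, lo, hi = odds_ratio_ci(50, 10, 10, 2)
    assert or_est == pytest.approx(1.0)
    # zero cell: Haldane-Anscombe correction on all four cells
    or_est, lo, hi = odds_ratio_ci(10, 5, 5, 0)
    assert or_est == pytest.approx((10.5 * 0.5) / (5.5 * 5.5), abs=1e-12)
    assert lo <= or_est <= hi


@given(st.tuples(*(st.integers(min_value=0, max_value=50),) * 4))
@settings(max_examples=200, deadline=None)
def test_ci_symmetric_about_or_on_log_scale(cells):
    a, b, c, d = cells
    or_est, lo, hi = odds_ratio_ci(a, b, c, d)
    assert math.log(or_est) - math.log(lo) == pytest.approx(
        math.log(hi) - math.log(or_est), rel=1e-9
    )


@given(
    st.tuples(*(st.integers(min_value=1, max_value=40),) * 4),
    st.integers(min_value=1, max_value=5),
)
@settings(max_examples=200, deadline=None)
def test_or_monotone_in_concordant_mass(cells, shift):
    """Moving mass from the discordant cells into (a, d) raises the OR."""
    a, b, c, d = cells
    if b <= shift or c <= shift:
        return
    before, *_ = odds_ratio_ci(a, b, c, d)
    after, *_ = odds_ratio_ci(a + shift, b - shift, c - shift, d + shift)
    assert after > before


def test_build_contingency_counts_each_cell():
    df = pd.DataFrame({
        "sample_id": list("wxyz"),
        "cohort": ["c"] * 4,
        "ESR1_status": ["WT", "Mut", "WT", "Mut"],
        "TP53_status": ["WT", "WT", "Mut", "Mut"],
        "histology": ["lobular", "ductal", "lobular", "lobular"],
    })
    res = build_contingency(df)
    assert res.counts() == (1, 1, 1, 1)
    lob = build_contingency(df, lambda d: d["histology"] == "lobular")
    assert lob.n_total == 3
    # missing statuses are excluded and flagged when nothing remains
    df2 = df.assign(ESR1_status=["NA"] * 4)
    res2 = build_contingency(df2)
    assert res2.flag == "empty_stratum" and res2.n_excluded == 4


def test_stratified_counts_conserve_the_global_table(genotypes):
    strata = {
        f"histology={lvl}": (lambda d, v=lvl: d["histology"] == v)
        for lvl in sorted(genotypes["histology"].unique())
    }
    results = stratified_screen(genotypes, strata)
    total = build_contingency(genotypes)
    for i in range(4):
        assert sum(r.counts()[i] for r in results) == total.counts()[i]


def test_small_stratum_flagged_without_p(genotypes):
    one = genotypes.head(1)
    res = evaluate_contingency(build_contingency(one))
    assert res.flag == "too_small" and math.isnan(res.p)


def test_planted_exclusivity_below_one_in_every_stratum():
    cfg = SynthConfig(n_samples_per_cohort=6000, target_or=0.2, seed=17)
    table = gen_genotypes(cfg)
    strata = {
        f"histology={lvl}": (lambda d, v=lvl: d["histology"] == v)
        for lvl in ("ductal", "lobular")
    }
    for res in stratified_screen(table, strata):
        assert res.odds_ratio < 1


def test_size_significance_correlation_cases():
    def mk(p, n):
        return ContingencyResult("s", 1, 1, 1, 1, n_total=n, p=p)

    r, _, flag = size_significance_correlation([mk(0.5, 10), mk(0.05, 100), mk(0.005, 1000)])
    assert flag == "" and r == pytest.approx(-1.0, abs=0.25)
    # three points exactly on a line
    r, _, _ = size_significance_correlation([mk(0.1, 10), mk(0.01, 20), mk(0.001, 30)])
    assert abs(r) == pytest.approx(1.0)
    _, _, flag = size_significance_correlation([mk(0.1, 10), mk(0.1, 20), mk(0.1, 30)])
    assert flag == "zero_variance"
    _, _, flag = size_significance_correlation([mk(0.1, 10), mk(0.2, 20)])
    assert flag == "fewer_than_3_strata"


def test_larger_strata_reach_smaller_p_under_constant_exclusivity():
    results = []
    for i, n in enumerate((250, 500, 1000, 2000, 4000)):
        cfg = SynthConfig(n_samples_per_cohort=n, target_or=0.2, seed=30 + i)
        results.append(evaluate_contingency(build_contingency(gen_genotypes(cfg))))
    r, _, flag = size_significance_correlation(results)
    assert flag == "" and r < 0


def test_dual_mutant_liver_enrichment_is_planted():
    cfg = SynthConfig(n_samples_per_cohort=8000, seed=19)
    out, flag = dual_mutant_enrichment(gen_genotypes(cfg), "met_site")
    assert flag == ""
    liver = out.set_index("level").loc["liver"]
    assert liver["or"] > 1 and liver["q"] < 0.05
    assert (out["q"] >= out["p"] - 1e-12).all()


def test_dual_mutant_enrichment_edge_cases():
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "cohort": ["c"] * 6,
        "ESR1_status": ["Mut", "Mut", "WT", "WT", "WT", "WT"],
        "TP53_status": ["Mut", "Mut", "Mut", "Mut", "Mut", "Mut"],
        "site": ["liver"] * 6,
    })
    out, flag = dual_mutant_enrichment(df, "site")
    assert flag == ""
    assert len(out) == 1 and out["q"].iloc[0] == out["p"].iloc[0]  # BH identity at m=1
    df_wt = df.assign(ESR1_status="WT")
    _, flag = dual_mutant_enrichment(df_wt, "site")
    assert flag == "no_dual_mutants"


def test_compare_vaf_exact_and_planted_shift():
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(4)],
        "cohort": ["c"] * 4,
        "ESR1_status": ["WT", "WT", "Mut", "Mut"],
        "TP53_status": ["Mut"] * 4,
        "TP53_vaf": [0.2, 0.4, 0.2, 0.4],
    })
    res = compare_vaf(df)
    assert res.p == pytest.approx(1.0)
    assert res.u_statistic + (res.n_wt * res.n_mut - res.u_statistic) == res.n_wt * res.n_mut

    rng = np.random.default_rng(23)
    big = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(200)],
        "cohort": ["c"] * 200,
        "ESR1_status": ["WT"] * 100 + ["Mut"] * 100,
        "TP53_status": ["Mut"] * 200,
        "TP53_vaf": np.concatenate([rng.beta(2, 5, 100), rng.beta(5, 2, 100)]),
    })
    res = compare_vaf(big)
    assert res.p < 0.01 and res.median_esr1_mut > res.median_esr1_wt

    empty = compare_vaf(df[df["ESR1_status"] == "WT"])
    assert empty.flag == "empty_group"
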