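"""Mutual-exclusivity statistics for two-gene genotype tables.

The central object is the 2x2 genotype contingency table for ESR1 and TP53
mutation status, laid out as

    a = n(ESR1 WT,  TP53 WT)     c = n(ESR1 WT,  TP53 Mut)
    b = n(ESR1 Mut, TP53 WT)     d = n(ESR1 Mut, TP53 Mut)

with odds ratio OR = a*d / (b*c). OR < 1 indicates a trend of mutual
exclusivity (the dual-mutant cell d is depleted relative to independence).
Significance comes from Fisher's exact test computed by minimum-likelihood
summation over the fixed-margins hypergeometric family; confidence intervals
are Woolf (log-normal) intervals on Haldane-Anscombe-corrected counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Relative tolerance on the point-probability comparison in the two-sided
#: Fisher summation (matches the convention of mainstream exact-test code).
_FISHER_RELTOL = 1e-7


# ---------------------------------------------------------------------------
# exact test and odds ratio
# ---------------------------------------------------------------------------

def fisher_family_pvalues(n_total: int, row1: int, col1: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every table in one fixed-margins family.

    Returns the support of the (1,1) cell count ``a`` and the p-value for each
    observed ``a``: the sum of hypergeometric point probabilities over tables
    at most as likely as the observed one (relative tolerance
    :data:`_FISHER_RELTOL`).
    """
    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n_total, row1, col1)
    # for each observed a, sum pmf over tables with pmf <= pmf(a)*(1+tol)
    thresh = pmf * (1.0 + _FISHER_RELTOL)
    pvals = np.array([pmf[pmf <= t].sum() for t in thresh])
    return support, np.minimum(pvals, 1.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for counts (a, b, c, d).

    Any zero margin makes the table degenerate: p = 1 by convention.
    """
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError(f"counts must be non-negative integers, got {(a, b, c, d)}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1, col1 = a + c, a + b  # ESR1-WT margin, TP53-WT margin
    if n_total == 0 or row1 in (0, n_total) or col1 in (0, n_total):
        logger.info("degenerate margin for table %s; p = 1 by convention", (a, b, c, d))
        return 1.0
    support, pvals = fisher_family_pvalues(n_total, row1, col1)
    return float(pvals[a - support[0]])


def odds_ratio_ci(
    a: int, b: int, c: int, d: int, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Woolf 1-alpha confidence interval.

    If any cell is zero, 0.5 is added to every cell (Haldane-Anscombe) before
    both the estimate and the interval; the exact test is never corrected.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if (cells < 0).any():
        raise ValueError("counts must be non-negative")
    if (cells == 0).any():
        cells = cells + 0.5
    ca, cb, cc, cd = cells
    or_est = (ca * cd) / (cb * cc)
    se = math.sqrt((1.0 / cells).sum())
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    log_or = math.log(or_est)
    return or_est, math.exp(log_or - z * se), math.exp(log_or + z * se)


# ---------------------------------------------------------------------------
# contingency construction and the stratified screen
# ---------------------------------------------------------------------------

@dataclass
class ContingencyResult:
    """One stratum's 2x2 counts with OR, CI and exact p."""

    stratum: str
    a: int
    b: int
    c: int
    d: int
    n_total: int = 0
    n_excluded: int = 0
    odds_ratio: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p: float = math.nan
    flag: str = ""

    def counts(self) -> tuple[int, int, int, int]:
        return self.a, self.b, self.c, self.d


def build_contingency(
    table: pd.DataFrame,
    stratum_filter: Callable[[pd.DataFrame], pd.Series] | None = None,
    stratum: str = "all",
) -> ContingencyResult:
    """Count the four ESR1 x TP53 genotype cells within one stratum.

    Samples failing the filter or with a missing gene status are excluded and
    counted in ``n_excluded``. An empty stratum yields a flagged result with
    no test.
    """
    df = table
    if stratum_filter is not None:
        df = df[stratum_filter(df).astype(bool)]
    n_candidate = len(df)
    ok = df["ESR1_status"].isin(["WT", "Mut"]) & df["TP53_status"].isin(["WT", "Mut"])
    df = df[ok]
    n_excluded = n_candidate - len(df)
    if n_excluded:
        logger.info("stratum %s: excluded %d samples with missing status", stratum, n_excluded)
    esr1_mut = (df["ESR1_status"] == "Mut").to_numpy()
    tp53_mut = (df["TP53_status"] == "Mut").to_numpy()
    a = int((~esr1_mut & ~tp53_mut).sum())
    b = int((esr1_mut & ~tp53_mut).sum())
    c = int((~esr1_mut & tp53_mut).sum())
    d = int((esr1_mut & tp53_mut).sum())
    res = ContingencyResult(stratum, a, b, c, d, n_total=a + b + c + d, n_excluded=n_excluded)
    if res.n_total == 0:
        res.flag = "empty_stratum"
    return res


def evaluate_contingency(res: ContingencyResult, alpha: float = 0.05) -> ContingencyResult:
    """Attach OR/CI/p to a contingency result in place (flagged strata skipped)."""
    if res.flag == "empty_stratum":
        return res
    if res.n_total < 2:
        res.flag = "too_small"
        return res
    res.odds_ratio, res.ci_low, res.ci_high = odds_ratio_ci(*res.counts(), alpha=alpha)
    res.p = fisher_exact_2x2(*res.counts())
    return res


def stratified_screen(
    table: pd.DataFrame,
    strata: dict[str, Callable[[pd.DataFrame], pd.Series]],
    alpha: float = 0.05,
) -> list[ContingencyResult]:
    """One ContingencyResult per named stratum predicate (forest-plot input)."""
    return [
        evaluate_contingency(build_contingency(table, pred, stratum=name), alpha=alpha)
        for name, pred in strata.items()
    ]


def results_to_frame(results: Iterable[ContingencyResult]) -> pd.DataFrame:
    rows = [
        {
            "stratum": r.stratum,
            "a": r.a,
            "b": r.b,
            "c": r.c,
            "d": r.d,
            "n": r.n_total,
            "or": r.odds_ratio,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "flag": r.flag,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def size_significance_correlation(
    results: Sequence[ContingencyResult],
) -> tuple[float, float, str]:
    """Pearson correlation of log10(p) against stratum size.

    Returns (r, p, flag); flag is non-empty when fewer than 3 usable strata
    exist or either axis has zero variance.
    """
    usable = [r for r in results if not r.flag and np.isfinite(r.p) and r.p > 0]
    if len(usable) < 3:
        return math.nan, math.nan, "fewer_than_3_strata"
    logp = np.log10([r.p for r in usable])
    sizes = np.array([r.n_total for r in usable], dtype=float)
    if np.ptp(logp) == 0 or np.ptp(sizes) == 0:
        return math.nan, math.nan, "zero_variance"
    r, p = stats.pearsonr(logp, sizes)
    return float(r), float(p), ""


# ---------------------------------------------------------------------------
# dual-mutant feature enrichment and VAF comparison
# ---------------------------------------------------------------------------

def dual_mutant_enrichment(
    table: pd.DataFrame, feature: str, alpha: float = 0.05
) -> tuple[pd.DataFrame, str]:
    """Per-level enrichment of a feature in dual mutants vs TP53-mut-only.

    For every level of ``feature`` among TP53-mutant samples, a 2x2 of
    (dual-mutant vs TP53-mut-only) x (level vs not) is tested with the exact
    test; q-values are Benjamini-Hochberg across levels.
    """
    tp53_mut = table[table["TP53_status"] == "Mut"]
    dual = tp53_mut["ESR1_status"] == "Mut"
    if int(dual.sum()) == 0:
        return pd.DataFrame(), "no_dual_mutants"
    feat = tp53_mut[feature].astype(str)
    rows = []
    for level in sorted(feat.dropna().unique()):
        in_level = (feat == level).to_numpy()
        a = int((dual.to_numpy() & in_level).sum())        # dual, level
        b = int((dual.to_numpy() & ~in_level).sum())       # dual, other
        c = int((~dual.to_numpy() & in_level).sum())       # only, level
        d = int((~dual.to_numpy() & ~in_level).sum())      # only, other
        # OR = (a*d)/(b*c) > 1 <=> level enriched among dual mutants
        or_est, lo, hi = odds_ratio_ci(a, b, c, d, alpha=alpha)
        p = fisher_exact_2x2(a, b, c, d)
        rows.append(
            {"level": level, "dual_level": a, "dual_other": b, "only_level": c,
             "only_other": d, "or": or_est, "ci_low": lo, "ci_high": hi, "p": p}
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out, ""


@dataclass
class VafComparison:
    u_statistic: float
    p: float
    median_esr1_wt: float
    median_esr1_mut: float
    n_wt: int = 0
    n_mut: int = 0
    flag: str = ""


def compare_vaf(table: pd.DataFrame, vaf_column: str = "TP53_vaf") -> VafComparison:
    """Mann-Whitney comparison of TP53 VAF between ESR1 WT and mutant tumors.

    Restricted to TP53-mutant samples with a recorded VAF. Exact enumeration
    when both groups have at most 8 samples, otherwise the normal
    approximation with continuity and tie correction.
    """
    df = table[(table["TP53_status"] == "Mut") & table[vaf_column].notna()]
    wt = df.loc[df["ESR1_status"] == "WT", vaf_column].to_numpy(dtype=float)
    mut = df.loc[df["ESR1_status"] == "Mut", vaf_column].to_numpy(dtype=float)
    if len(wt) == 0 or len(mut) == 0:
        return VafComparison(math.nan, math.nan, math.nan, math.nan,
                             len(wt), len(mut), flag="empty_group")
    method = "exact" if (len(wt) <= 8 and len(mut) <= 8) else "asymptotic"
    res = stats.mannwhitneyu(wt, mut, alternative="two-sided", method=method)
    return VafComparison(
        float(res.statistic), float(min(res.pvalue, 1.0)),
        float(np.median(wt)), float(np.median(mut)), len(wt), len(mut),
    )
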