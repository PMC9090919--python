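"""Count normalization and the ER-status calibration algorithm.

TMM (trimmed mean of M-values) scaling factors are computed from raw counts
against a reference sample, counts are converted to log2(CPM + 1), microarray
probes are collapsed to genes by maximum inter-quartile range, and pathology
ER status is calibrated against ESR1 expression by scanning cutoffs in steps
of 0.1 between the first and third quartile of the target cohort, keeping the
cutoff with the highest concordance to pathology labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM / CPM
# ---------------------------------------------------------------------------

def tmm_factors(
    counts: ExpressionMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """Per-sample TMM scaling factors, renormalized to multiply to 1.

    The reference is the sample whose upper-quartile expression (counts over
    library size) is closest to the mean upper-quartile, unless given. For
    each sample, gene-wise log2 ratios M and mean log2 abundances A against
    the reference are computed over genes observed in both; the extreme
    ``trim_m`` of each M tail and ``trim_a`` of each A tail are discarded and
    the factor is 2 to the precision-weighted mean of the remaining M values.
    """
    if counts.scale != "raw_counts":
        raise ValueError("tmm_factors requires a raw_counts matrix")
    mat = counts.data.to_numpy(dtype=float)
    samples = list(counts.samples)
    if len(samples) < 2:
        raise ValueError("TMM needs at least two samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        bad = [samples[i] for i in np.flatnonzero(lib == 0)]
        raise ValueError(f"sample(s) with zero total count: {bad}")

    props = mat / lib  # per-sample composition
    if ref_sample is None:
        uq = np.quantile(props, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        if ref_sample not in samples:
            raise ValueError(f"reference sample {ref_sample!r} not in matrix")
        ref_idx = samples.index(ref_sample)

    factors = np.ones(len(samples))
    pr = props[:, ref_idx]
    yr = mat[:, ref_idx]
    nr = lib[ref_idx]
    for k in range(len(samples)):
        if k == ref_idx:
            continue
        pk, yk, nk = props[:, k], mat[:, k], lib[k]
        both = (yk > 0) & (yr > 0)
        if both.sum() == 0:
            logger.warning("no shared expressed genes for sample %s; factor 1", samples[k])
            continue
        m = np.log2(pk[both] / pr[both])
        a = 0.5 * np.log2(pk[both] * pr[both])
        w = (nk - yk[both]) / (nk * yk[both]) + (nr - yr[both]) / (nr * yr[both])
        n = len(m)
        # double (two-tail) trimming by rank, as in the published procedure
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        rank_m = pd.Series(m).rank(method="average").to_numpy()
        rank_a = pd.Series(a).rank(method="average").to_numpy()
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.sum() == 0 or not np.isfinite(w[keep]).all() or w[keep].sum() == 0:
            logger.warning("TMM trim left no usable genes for %s; factor 1", samples[k])
            continue
        factors[k] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))  # product-to-1
    return pd.Series(factors, index=samples, name="tmm_factor")


def cpm_log(counts: ExpressionMatrix, factors: pd.Series | None = None) -> ExpressionMatrix:
    """log2(CPM + 1) with optional TMM effective library sizes."""
    if counts.scale != "raw_counts":
        raise ValueError("cpm_log requires a raw_counts matrix")
    lib = counts.data.sum(axis=0)
    if factors is not None:
        lib = lib * factors.reindex(counts.samples)
    if (lib == 0).any():
        raise ValueError("zero effective library size")
    cpm = counts.data * 1e6 / lib
    return ExpressionMatrix(np.log2(cpm + 1.0), "log2cpm1")


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_to_gene: dict[str, str]
) -> ExpressionMatrix:
    """Collapse probes to genes, keeping the probe with the highest IQR.

    Ties on IQR go to the lexicographically smallest probe id. Probes without
    a gene mapping are dropped (logged).
    """
    df = probe_matrix.data
    mapped = [p for p in df.index if p in probe_to_gene]
    dropped = len(df) - len(mapped)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    vals = df.loc[mapped]
    iqr = vals.quantile(0.75, axis=1) - vals.quantile(0.25, axis=1)
    choice = (
        pd.DataFrame({
            "probe": mapped,
            "gene": [probe_to_gene[p] for p in mapped],
            "iqr": iqr.to_numpy(),
        })
        .sort_values(["gene", "iqr", "probe"], ascending=[True, False, True])
        .drop_duplicates("gene", keep="first")
    )
    out = vals.loc[choice["probe"]]
    out.index = choice["gene"].to_numpy()
    return ExpressionMatrix(out.sort_index(), probe_matrix.scale)


# ---------------------------------------------------------------------------
# ER-status calibration
# ---------------------------------------------------------------------------

@dataclass
class ErCalibration:
    """Result of the cutoff scan: grid, winner and per-cutoff concordance."""

    cutoff_grid: np.ndarray
    chosen_cutoff: float
    concordance: float
    table: pd.DataFrame  # columns cutoff, concordance
    n_reference: int
    n_label_missing: int


def _cutoff_grid(target_expr: np.ndarray, step: float = 0.1) -> np.ndarray:
    q1, q3 = np.quantile(target_expr, [0.25, 0.75])
    lo, hi = round(float(q1), 1), round(float(q3), 1)
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


def calibrate_er_cutoff(
    ref_expr, ref_labels, target_expr, step: float = 0.1
) -> ErCalibration:
    """Scan ESR1 cutoffs against pathology labels of a reference cohort.

    The grid runs in ``step`` increments over the closed interval between the
    first and third quartiles of the target cohort's ESR1 values. A reference
    sample is predicted positive iff its value is >= the cutoff; concordance
    is the fraction of predictions matching pathology. Samples with a missing
    pathology label are excluded from the denominator and counted.
    """
    ref_expr = np.asarray(ref_expr, dtype=float)
    labels = np.asarray([str(x) for x in ref_labels], dtype=object)
    if len(ref_expr) != len(labels):
        raise ValueError("ref_expr and ref_labels must align")
    known = np.isin(labels, ("pos", "neg"))
    n_missing = int((~known).sum())
    if n_missing:
        logger.info("calibrate_er_cutoff: %d reference labels missing, excluded", n_missing)
    ref_expr, labels = ref_expr[known], labels[known]
    if len(ref_expr) == 0 or len(np.unique(labels)) < 2:
        raise ValueError("degenerate calibration: reference labels are all identical or absent")
    is_pos = labels == "pos"
    grid = _cutoff_grid(np.asarray(target_expr, dtype=float), step=step)
    conc = np.array([np.mean((ref_expr >= c) == is_pos) for c in grid])
    best = int(np.argmax(conc))  # argmax takes the first (smallest) maximizer
    table = pd.DataFrame({"cutoff": grid, "concordance": conc})
    return ErCalibration(grid, float(grid[best]), float(conc[best]), table,
                         n_reference=len(ref_expr), n_label_missing=n_missing)


def predict_er_status(target_expr, cutoff: float) -> np.ndarray:
    """Predict pos/neg per sample: positive iff value >= cutoff."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    vals = np.asarray(target_expr, dtype=float)
    out = np.where(vals >= cutoff, "pos", "neg")
    logger.info("predict_er_status: %d pos / %d neg at cutoff %.2f",
                int((out == "pos").sum()), int((out == "neg").sum()), cutoff)
    return out


def filter_er_cell_lines(
    expr: ExpressionMatrix, threshold: float = 3.0, gene: str = "ESR1"
) -> list[str]:
    """Samples (cell lines) with ESR1 expression strictly above the threshold."""
    row = expr.row(gene)
    kept = [s for s in expr.samples if row[s] > threshold]
    logger.info("filter_er_cell_lines: kept %d / %d samples", len(kept), len(expr.samples))
    return kept
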