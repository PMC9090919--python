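"""Peak-centric analyses: window annotation, overlap tests, dual-mechanism calls.

Genes are annotated to a peak set when their strand-aware TSS lies within a
fixed window (default +/-100 kb) of any peak boundary (a TSS inside a peak
is at distance 0). Datasets are filtered by annotated-target count (strictly
more than 1000 by default) and their union taken. Overlap between two peak
sets is asymmetric: the fraction of query peaks sharing at least one base
with any subject peak. Significance comes from a randomized-region null that
relocates every query peak uniformly within its own chromosome, preserving
the per-chromosome peak count and width multiset; randomized overlap counts
are pooled into a 2x2 exact test, with an empirical permutation p-value as a
cross-check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GeneModel, PeakSet, SignatureSet
from .mutex_stats import fisher_exact_2x2

logger = logging.getLogger(__name__)

WINDOW = 100_000
MIN_TARGETS = 1000


# ---------------------------------------------------------------------------
# window annotation
# ---------------------------------------------------------------------------

def _merged_intervals(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted [start, end) rows into disjoint intervals."""
    starts, ends = [], []
    cur_s, cur_e = int(arr[0, 0]), int(arr[0, 1])
    for s, e in arr[1:]:
        if s <= cur_e:
            cur_e = max(cur_e, int(e))
        else:
            starts.append(cur_s)
            ends.append(cur_e)
            cur_s, cur_e = int(s), int(e)
    starts.append(cur_s)
    ends.append(cur_e)
    return np.asarray(starts), np.asarray(ends)


def annotate_genes_near_peaks(
    peaks: PeakSet, genes: GeneModel, window: int = WINDOW
) -> set[str]:
    """Gene ids whose TSS is within ``window`` bp of any peak.

    Raises if the two inputs share no chromosome names (naming mismatch).
    """
    peak_chroms = peaks.by_chrom()
    gene_chroms = set(genes.genes["chrom"].unique())
    if not gene_chroms & set(peak_chroms):
        raise ValueError(
            f"no shared chromosome names between peaks {sorted(peak_chroms)[:5]} "
            f"and genes {sorted(gene_chroms)[:5]}"
        )
    annotated: set[str] = set()
    for chrom, grp in genes.genes.groupby("chrom", sort=False):
        if chrom not in peak_chroms:
            continue
        arr = peak_chroms[chrom].astype(np.int64).copy()
        arr[:, 0] -= window
        arr[:, 1] += window
        starts, ends = _merged_intervals(arr)
        tss = grp["tss"].to_numpy(dtype=np.int64)
        idx = np.searchsorted(starts, tss, side="right") - 1
        inside = (idx >= 0) & (tss < ends[np.clip(idx, 0, len(ends) - 1)])
        annotated.update(grp.loc[inside, "gene"])
    return annotated


@dataclass
class AnnotationResult:
    per_dataset: dict[str, set[str]]
    retained: list[str]
    union_genes: set[str]
    min_targets: int
    window: int = WINDOW
    flag: str = ""


def filter_union_targets(
    per_dataset: dict[str, set[str]], min_targets: int = MIN_TARGETS,
    window: int = WINDOW,
) -> AnnotationResult:
    """Keep datasets with strictly more than ``min_targets`` annotated genes."""
    if not per_dataset:
        raise ValueError("need at least one dataset")
    retained = [name for name, g in per_dataset.items() if len(g) > min_targets]
    union: set[str] = set()
    for name in retained:
        union |= per_dataset[name]
    flag = "" if retained else "empty_union"
    if flag:
        logger.warning("filter_union_targets: every dataset fell below %d targets", min_targets)
    return AnnotationResult(per_dataset, retained, union, min_targets, window, flag)


# ---------------------------------------------------------------------------
# overlap statistics
# ---------------------------------------------------------------------------

def overlap_fraction(a: PeakSet, b: PeakSet) -> tuple[int, float]:
    """(count, fraction) of A peaks sharing >= 1 bp with any B peak.

    Asymmetric: A is the query; each A peak counts at most once.
    """
    if len(a) == 0:
        raise ValueError("query peak set is empty")
    b_chroms = b.by_chrom()
    n_overlapping = 0
    for chrom, arr_a in a.by_chrom().items():
        if chrom not in b_chroms:
            continue
        arr_b = b_chroms[chrom]
        b_starts = arr_b[:, 0]
        prefix_max_end = np.maximum.accumulate(arr_b[:, 1])
        # A peak [s, e) overlaps some B iff a B with start < e has end > s
        idx = np.searchsorted(b_starts, arr_a[:, 1], side="left")
        hit = (idx > 0) & (prefix_max_end[np.clip(idx - 1, 0, None)] > arr_a[:, 0])
        n_overlapping += int(hit.sum())
    return n_overlapping, n_overlapping / len(a)


def randomize_regions(
    a: PeakSet, chrom_sizes: dict[str, int], n_sets: int, seed: int
) -> list[PeakSet]:
    """Random relocations of every peak within its own chromosome.

    Each random set preserves the per-chromosome peak count and width
    multiset; new starts are uniform on [0, chrom_len - width]. Overlaps
    among random peaks are permitted.
    """
    df = a.intervals
    widths = (df["end"] - df["start"]).to_numpy(dtype=np.int64)
    chroms = df["chrom"].to_numpy()
    lens = np.array([chrom_sizes[c] for c in chroms], dtype=np.int64)
    if (widths > lens).any():
        bad = df.index[widths > lens][:5].tolist()
        raise ValueError(f"peak(s) wider than their chromosome: rows {bad}")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_sets):
        starts = rng.integers(0, lens - widths + 1)
        out.append(PeakSet(
            pd.DataFrame({"chrom": chroms, "start": starts, "end": starts + widths}),
            source=f"{a.source}_random{i}",
        ))
    return out


@dataclass
class OverlapTest:
    n_overlapping: int
    n_total: int
    overlap_fraction: float
    random_fractions: list[float] = field(default_factory=list)
    p: float = float("nan")           # pooled-count exact test
    p_empirical: float = float("nan")  # permutation-style cross-check


def overlap_significance(
    a: PeakSet, b: PeakSet, chrom_sizes: dict[str, int],
    n_sets: int = 100, seed: int = 0,
) -> OverlapTest:
    """Test whether A overlaps B more than randomized relocations of A do.

    The observed (overlapping, non-overlapping) counts are compared against
    the pooled counts over ``n_sets`` randomized sets in a 2x2 exact test.
    The per-set random overlap fractions give an empirical p-value
    (1 + #{random >= observed}) / (n_sets + 1) as a cross-check.
    """
    k_obs, frac_obs = overlap_fraction(a, b)
    n = len(a)
    random_counts = []
    for rand in randomize_regions(a, chrom_sizes, n_sets, seed):
        k, _ = overlap_fraction(rand, b)
        random_counts.append(k)
    pooled_k = int(sum(random_counts))
    p = fisher_exact_2x2(k_obs, n - k_obs, pooled_k, n_sets * n - pooled_k)
    p_emp = (1 + sum(k >= k_obs for k in random_counts)) / (n_sets + 1)
    return OverlapTest(
        k_obs, n, frac_obs, [k / n for k in random_counts], p, p_emp
    )


# ---------------------------------------------------------------------------
# dual-mechanism classification
# ---------------------------------------------------------------------------

@dataclass
class DualMechanismReport:
    """Four-way partition of signature genes by regulatory mechanism."""

    both: set[str]
    chip_only: set[str]
    mirna_only: set[str]
    neither: set[str]
    n_signature: int
    union_count: int
    union_pct: float   # percent of signature covered by either mechanism
    both_pct: float    # percent covered by both

    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "chip_only": len(self.chip_only),
            "mirna_only": len(self.mirna_only),
            "neither": len(self.neither),
        }


def dual_mechanism_classify(
    signature: SignatureSet, chip_genes: set[str], mirna_target_genes: set[str]
) -> DualMechanismReport:
    """Partition signature genes by WT-p53 binding vs miRNA-target annotation."""
    members = set(signature.members)
    if not members:
        raise ValueError("empty signature")
    chip = members & set(chip_genes)
    mirna = members & set(mirna_target_genes)
    both = chip & mirna
    union = chip | mirna
    report = DualMechanismReport(
        both=both,
        chip_only=chip - mirna,
        mirna_only=mirna - chip,
        neither=members - union,
        n_signature=len(members),
        union_count=len(union),
        union_pct=round(100.0 * len(union) / len(members), 1),
        both_pct=round(100.0 * len(both) / len(members), 1),
    )
    return report
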