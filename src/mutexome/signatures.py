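"""Single-sample gene-set enrichment scoring and signature derivation.

The scorer follows the GSVA design for continuous log-scale data: each
gene's expression is replaced by its empirical CDF across samples, genes are
ranked per sample, and a weighted random walk down the ranked list (members
weighted by the centered rank statistic, non-members by a uniform decrement)
yields a per-sample enrichment score equal to the signed sum of the maximum
positive and maximum negative deviations. The score is therefore invariant
to gene-row order and to any strictly monotone per-gene transform.

Signature derivation reproduces the dual-cohort rule: genes of a fixed
universe are tested per cohort (two-sided Mann-Whitney, Benjamini-Hochberg
over the universe), and the cross-cohort intersections of consistently
down-regulated and consistently unchanged genes form the two derived sets.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import LOG_SCALES, ExpressionMatrix, SignatureSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# enrichment scoring
# ---------------------------------------------------------------------------

def gsva_score(
    expr: ExpressionMatrix, sets: Sequence[SignatureSet], tau: float = 1.0
) -> pd.DataFrame:
    """Per-(sample, set) enrichment scores; rows are sets, columns samples.

    Sets with an empty intersection with the matrix are dropped with a
    warning; partial intersections are logged.
    """
    if expr.scale not in LOG_SCALES:
        raise ValueError(f"gsva_score expects a log-scale matrix, got {expr.scale!r}")
    if expr.data.shape[1] < 3:
        raise ValueError("gsva_score needs at least 3 samples")
    x = expr.data.to_numpy(dtype=float)
    p, n = x.shape
    genes = pd.Index(expr.features)

    # across-sample empirical CDF per gene (average ranks / n)
    ecdf = stats.rankdata(x, axis=1, method="average") / n

    masks: list[np.ndarray] = []
    kept_sets: list[SignatureSet] = []
    for s in sets:
        mask = genes.isin(s.members)
        k = int(mask.sum())
        if k == 0:
            logger.warning("set %s has no genes in the matrix; dropped", s.name)
            continue
        if k == p:
            raise ValueError(f"set {s.name!r} covers the whole matrix; no non-members")
        if k < len(s.members):
            logger.info("set %s: %d of %d members present", s.name, k, len(s.members))
        masks.append(mask)
        kept_sets.append(s)
    if not kept_sets:
        raise ValueError("no set intersects the expression matrix")

    # per-sample ranks of the transformed values (1 = highest), ties averaged
    ranks = stats.rankdata(-ecdf, axis=0, method="average")
    rank_stat = np.abs((p + 1) / 2.0 - ranks)  # centered rank statistic
    weights = rank_stat ** tau

    out = np.empty((len(kept_sets), n))
    # exact ECDF ties are broken by lexicographic gene id, which keeps the
    # score invariant under any permutation of the gene rows
    id_rank = np.argsort(np.argsort(genes.to_numpy().astype(str)))
    for j in range(n):
        order = np.lexsort((id_rank, -ecdf[:, j]))
        w_j = weights[order, j]
        for si, mask in enumerate(masks):
            m = mask[order]
            k = int(m.sum())
            inc = np.where(m, w_j, 0.0)
            wsum = inc.sum()
            if wsum == 0:  # degenerate: all member weights zero
                inc = np.where(m, 1.0 / k, 0.0)
            else:
                inc /= wsum
            dec = np.where(m, 0.0, 1.0 / (p - k))
            walk = np.cumsum(inc - dec)
            out[si, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.DataFrame(out, index=[s.name for s in kept_sets], columns=expr.samples)


# ---------------------------------------------------------------------------
# differential screen and dual-cohort derivation
# ---------------------------------------------------------------------------

def de_screen(
    expr: ExpressionMatrix,
    mutant_labels: Sequence[bool],
    universe: SignatureSet,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-universe-gene differential call between mutant and WT samples.

    Two-sided Mann-Whitney per gene; Benjamini-Hochberg over exactly the
    universe. Direction is the sign of (mutant median - WT median) for genes
    with q below the FDR cutoff, else ``unchanged``.
    """
    labels = np.asarray(mutant_labels, dtype=bool)
    if len(labels) != expr.data.shape[1]:
        raise ValueError("labels must align with samples")
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValueError("both groups need at least 3 samples")
    present = [g for g in universe.members if g in expr.data.index]
    if len(present) < len(universe.members):
        raise ValueError(
            f"universe gene(s) missing from matrix: "
            f"{sorted(set(universe.members) - set(present))[:5]}"
        )
    sub = expr.data.loc[list(universe.members)].to_numpy(dtype=float)
    mut, wt = sub[:, labels], sub[:, ~labels]
    res = stats.mannwhitneyu(mut, wt, axis=1, alternative="two-sided", method="asymptotic")
    pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    delta = np.median(mut, axis=1) - np.median(wt, axis=1)
    direction = np.where(
        qvals < fdr, np.where(delta > 0, "up", np.where(delta < 0, "down", "unchanged")),
        "unchanged",
    )
    return pd.DataFrame(
        {"p": pvals, "q": qvals, "median_diff": delta, "direction": direction},
        index=list(universe.members),
    )


def derive_signatures(
    results_cohort1: pd.DataFrame,
    results_cohort2: pd.DataFrame,
    universe: SignatureSet,
    cohort_names: tuple[str, str] = ("cohort1", "cohort2"),
    fdr: float = 0.01,
) -> tuple[SignatureSet, SignatureSet]:
    """Intersect two cohorts' differential calls over a shared universe.

    Returns the consistently-down set (the p53-associated estrogen-response
    signature) and the consistently-unchanged set; the two are disjoint by
    construction.
    """
    for res in (results_cohort1, results_cohort2):
        if set(res.index) != set(universe.members):
            raise ValueError("result tables must cover exactly the universe")
    d1 = results_cohort1["direction"]
    d2 = results_cohort2["direction"]
    down = [g for g in universe.members if d1[g] == "down" and d2[g] == "down"]
    unchanged = [g for g in universe.members if d1[g] == "unchanged" and d2[g] == "unchanged"]
    prov = {"cohorts": list(cohort_names), "test": "mann-whitney", "fdr": fdr,
            "universe": universe.name}
    tp53_er = SignatureSet("TP53-ER", tuple(down), {**prov, "direction": "down_in_both"})
    non_tp53_er = SignatureSet(
        "Non-TP53-ER", tuple(unchanged), {**prov, "direction": "unchanged_in_both"}
    )
    return tp53_er, non_tp53_er


# ---------------------------------------------------------------------------
# per-patient trajectories
# ---------------------------------------------------------------------------

def trajectory_scores(scores: pd.DataFrame, patient_map: pd.DataFrame) -> pd.DataFrame:
    """Order per-sample scores primary-first within patients, with deltas.

    ``patient_map`` columns: sample_id, patient, lesion (the primary sample
    has lesion == 'primary'), plus optional genotype columns carried through.
    A sample mapped to two patients is an input error; a patient without
    exactly one primary is flagged and its deltas omitted.
    """
    required = {"sample_id", "patient", "lesion"}
    if not required <= set(patient_map.columns):
        raise ValueError(f"patient_map needs columns {sorted(required)}")
    if patient_map["sample_id"].duplicated().any():
        dup = patient_map.loc[patient_map["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"sample(s) mapped more than once: {dup[:5]}")
    rows = []
    carry = [c for c in patient_map.columns if c not in required]
    for patient, grp in patient_map.groupby("patient", sort=True):
        primaries = grp[grp["lesion"] == "primary"]
        flag = "" if len(primaries) == 1 else "no_unique_primary"
        ordered = pd.concat([primaries, grp[grp["lesion"] != "primary"].sort_values("lesion")])
        for set_name in scores.index:
            base = (
                float(scores.loc[set_name, primaries["sample_id"].iloc[0]])
                if not flag else np.nan
            )
            for _, rec in ordered.iterrows():
                score = float(scores.loc[set_name, rec["sample_id"]])
                rows.append({
                    "patient": patient,
                    "lesion": rec["lesion"],
                    "sample_id": rec["sample_id"],
                    "set": set_name,
                    "score": score,
                    "delta_vs_primary": (score - base) if not flag else np.nan,
                    "flag": flag,
                    **{c: rec[c] for c in carry},
                })
    return pd.DataFrame(rows)
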