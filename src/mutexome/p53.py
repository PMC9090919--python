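"""Functional classification of mutant p53.

Missense variants carry a loss-of-function score (LOFS): the mean residual
transactivation, as a percentage of WT p53, across the canonical p53 target
promoters assayed for that variant (WAF1, MDM2, BAX, 14-3-3-s, AIP, NOXA,
p53R2, ...). Classes: strong (< 1% of WT activity), medium (1-10%, boundaries
closed), weak (> 10%). Non-missense variants are unclassified. Gain-of-function
status is an exact catalog lookup after normalizing the protein-change
notation. The immunohistochemistry rule converts percent-positive nuclear
staining into null-aberrant (0-15), wildtype (16-79) or positive-aberrant
(80-100) after half-up rounding.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOFS_CLASSES = ("strong", "medium", "weak", "unclassified")

#: Canonical target promoters; a LOFS table may report 7 or 8 of them.
PROMOTERS = ("WAF1", "MDM2", "BAX", "14-3-3-s", "AIP", "NOXA", "p53R2", "GADD45")


def lofs_score(promoter_values: Iterable[float]) -> float:
    """Mean transactivation percentage over non-missing promoter values.

    Returns NaN (unclassified downstream) when every value is missing.
    """
    vals = np.asarray(list(promoter_values), dtype=float)
    present = vals[~np.isnan(vals)]
    n_missing = len(vals) - len(present)
    if n_missing:
        logger.info("lofs_score: %d missing promoter value(s)", n_missing)
    if len(present) == 0:
        return math.nan
    return float(present.mean())


def lofs_classify(lofs: float) -> str:
    """strong if < 1, medium if in [1, 10], weak if > 10; NaN -> unclassified."""
    if isinstance(lofs, float) and math.isnan(lofs):
        return "unclassified"
    if not math.isfinite(lofs) or lofs < 0:
        raise ValueError(f"LOFS must be a finite non-negative percentage, got {lofs}")
    if lofs < 1.0:
        return "strong"
    if lofs <= 10.0:
        return "medium"
    return "weak"


def normalize_protein_change(protein_change: str) -> str:
    return protein_change.strip().removeprefix("p.").removeprefix("P.").upper()


def gof_classify(protein_change: str, gof_catalog: set[str] | frozenset[str]) -> str:
    """'GoF' iff the normalized protein change is in the (missense) catalog."""
    if not gof_catalog:
        raise ValueError("empty gain-of-function catalog")
    catalog = {normalize_protein_change(v) for v in gof_catalog}
    return "GoF" if normalize_protein_change(protein_change) in catalog else "other"


def ihc_classify(percent_positive: float) -> str:
    """p53 IHC interpretation on percent positive nuclei in [0, 100]."""
    if not (0.0 <= percent_positive <= 100.0):
        raise ValueError(f"percent positive {percent_positive} outside [0, 100]")
    value = math.floor(percent_positive + 0.5)  # half-up rounding
    if value <= 15:
        return "null_aberrant"
    if value <= 79:
        return "wildtype"
    return "positive_aberrant"


# ---------------------------------------------------------------------------
# table-level helpers
# ---------------------------------------------------------------------------

def read_lofs_table(path) -> pd.DataFrame:
    """Read a LOFS TSV (protein_change + promoter columns) -> per-variant scores."""
    df = pd.read_csv(path, sep="\t")
    if "protein_change" not in df.columns:
        raise ValueError("LOFS table needs a protein_change column")
    promoter_cols = [c for c in df.columns if c != "protein_change"]
    if not 7 <= len(promoter_cols) <= 8:
        raise ValueError(f"expected 7-8 promoter columns, found {len(promoter_cols)}")
    out = pd.DataFrame({
        "protein_change": df["protein_change"].map(normalize_protein_change),
        "lofs": [lofs_score(row) for row in df[promoter_cols].to_numpy(dtype=float)],
    })
    out["lofs_class"] = out["lofs"].map(lofs_classify)
    return out


def classify_genotypes(
    genotypes: pd.DataFrame,
    lofs_table: pd.DataFrame | None = None,
    gof_catalog: set[str] | None = None,
) -> pd.DataFrame:
    """Augment a genotype table with LOFS and GoF class columns.

    Only TP53 missense variants with a protein change present in the LOFS
    table receive a class; everything else is 'unclassified' / 'other'.
    """
    out = genotypes.copy()
    is_missense = (out.get("TP53_status") == "Mut") & (out.get("TP53_class") == "missense")
    pc = out.get("protein_change", pd.Series("", index=out.index)).fillna("")
    norm = pc.map(lambda v: normalize_protein_change(v) if v else "")

    lofs_class = pd.Series("unclassified", index=out.index)
    if lofs_table is not None:
        lookup = dict(zip(lofs_table["protein_change"], lofs_table["lofs_class"]))
        hit = is_missense & norm.isin(lookup)
        lofs_class[hit] = norm[hit].map(lookup)
    out["lofs_class"] = lofs_class

    gof = pd.Series("other", index=out.index)
    if gof_catalog:
        catalog = {normalize_protein_change(v) for v in gof_catalog}
        gof[is_missense & norm.isin(catalog)] = "GoF"
    out["gof_class"] = gof
    return out
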