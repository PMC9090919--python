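"""Anti-ESR1 miRNA screen: seed-site matching and correlation filtering.

A miRNA is a candidate ESR1 regulator when the sense strand of the ESR1
transcript carries a canonical seed site for it:

* ``7mer-m8`` - reverse complement of miRNA positions 2-8;
* ``7mer-A1`` - reverse complement of positions 2-7 followed by an A
  (the adenosine across from miRNA position 1);
* ``8mer``   - both conditions at the same locus, reported once as 8mer.

Candidates whose expression shows a strictly negative correlation with ESR1
mRNA across tumors are selected; the full candidate table, including
rejections, is always returned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, SignatureSet
from .signatures import gsva_score

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGT", "TGCA")

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class SeedSite:
    site_type: str
    offset: int  # 0-based start of the site on the transcript sense strand


def _revcomp_dna(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t").upper()


def seed_sites(mature: str, transcript: str) -> list[SeedSite]:
    """All canonical seed sites of a mature miRNA on a transcript.

    ``mature`` is an RNA string (5'->3', alphabet ACGU, length >= 8);
    ``transcript`` may use the DNA or RNA alphabet. Overlapping sites are all
    reported; a locus satisfying the 8mer definition is reported once, as an
    8mer, suppressing its constituent 7mer calls.
    """
    m = mature.upper()
    if len(m) < 8:
        raise ValueError("mature miRNA must be at least 8 nt")
    if set(m) - set("ACGU"):
        raise ValueError(f"mature sequence has non-ACGU characters: {sorted(set(m) - set('ACGU'))}")
    t = _rna_to_dna(transcript)
    if set(t) - set("ACGT"):
        raise ValueError(f"transcript has non-ACGT characters: {sorted(set(t) - set('ACGT'))}")

    m_dna = _rna_to_dna(m)
    rc7 = _revcomp_dna(m_dna[1:8])  # pairs miRNA positions 2-8; 5' base pairs pos 8
    rc6 = _revcomp_dna(m_dna[1:7])  # pairs positions 2-7
    m8_comp = rc7[0]                # the base complementary to miRNA position 8

    sites: list[SeedSite] = []
    for i in range(len(t) - 6):
        if t[i : i + 7] == rc7:
            if i + 7 < len(t) and t[i + 7] == "A":
                sites.append(SeedSite("8mer", i))
            else:
                sites.append(SeedSite("7mer-m8", i))
    for i in range(len(t) - 6):
        if t[i : i + 6] == rc6 and t[i + 6] == "A":
            if i >= 1 and t[i - 1] == m8_comp:
                continue  # part of an 8mer reported at i - 1
            sites.append(SeedSite("7mer-A1", i))
    return sorted(sites, key=lambda s: (s.offset, SITE_TYPES.index(s.site_type)))


def site_table(mature_seqs: dict[str, str], transcript: str) -> dict[str, list[SeedSite]]:
    """Seed sites for every mature sequence against one transcript."""
    return {mid: seed_sites(seq, transcript) for mid, seq in mature_seqs.items()}


# ---------------------------------------------------------------------------
# correlation screen
# ---------------------------------------------------------------------------

def screen_mirnas(
    mirna_expr: ExpressionMatrix,
    esr1_values: pd.Series,
    sites: dict[str, list[SeedSite]],
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate seed-matched miRNAs with ESR1 expression; select r < 0.

    Returns one row per miRNA with at least one seed site: number of sites,
    correlation, and the strict r < 0 selection flag. Zero-variance miRNAs
    are kept in the table but flagged and never selected.
    """
    common = mirna_expr.samples.intersection(esr1_values.index)
    if len(common) < 10:
        raise ValueError("screen needs at least 10 shared samples")
    if len(common) < len(mirna_expr.samples):
        logger.info("screen_mirnas: %d of %d samples shared with ESR1 vector",
                    len(common), len(mirna_expr.samples))
    esr1 = esr1_values.loc[common].to_numpy(dtype=float)
    rows = []
    for mid in mirna_expr.features:
        mirna_sites = sites.get(mid, [])
        if not mirna_sites:
            continue
        vals = mirna_expr.data.loc[mid, common].to_numpy(dtype=float)
        if np.std(vals) == 0:
            logger.warning("miRNA %s has zero variance; correlation undefined", mid)
            rows.append({"mirna_id": mid, "n_sites": len(mirna_sites), "r": np.nan,
                         "selected": False, "flag": "zero_variance"})
            continue
        if method == "pearson":
            r = float(stats.pearsonr(vals, esr1).statistic)
        elif method == "spearman":
            r = float(stats.spearmanr(vals, esr1).statistic)
        else:
            raise ValueError(f"unknown correlation method {method!r}")
        rows.append({"mirna_id": mid, "n_sites": len(mirna_sites), "r": r,
                     "selected": bool(r < 0), "flag": ""})
    return pd.DataFrame(rows, columns=["mirna_id", "n_sites", "r", "selected", "flag"])


def mirna_set_score(
    mirna_expr: ExpressionMatrix, selected_ids: list[str],
    set_name: str = "ESR1-targeting-miRNA",
) -> pd.Series:
    """Per-sample abundance score of the selected miRNA set (rank-based)."""
    if not selected_ids:
        raise ValueError("selected miRNA set is empty")
    sig = SignatureSet(set_name, tuple(selected_ids), {"source": "mirna_screen"})
    scores = gsva_score(mirna_expr, [sig])
    return scores.loc[set_name]
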