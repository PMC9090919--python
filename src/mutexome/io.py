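"""Readers and writers for the plain-text formats the pipeline touches.

All tabular formats are TSV. BED intervals are 0-based half-open; gene-model
TSS coordinates are 1-based on disk and converted to 0-based points here (the
only place the conversion happens). Missing VAF is encoded as an empty string
on disk, never as 0, because 0 is a legal allele frequency.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    GENE_STATUSES,
    MUTATION_CLASSES,
    ExpressionMatrix,
    GeneModel,
    PeakSet,
)

logger = logging.getLogger(__name__)

GENOTYPE_REQUIRED = ("sample_id", "cohort", "ESR1_status", "TP53_status")
ER_PATHOLOGY_LEVELS = ("pos", "neg", "missing")


class FormatError(ValueError):
    """A file failed validation; the message names the offending row."""


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def validate_genotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GENOTYPE_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"genotype table missing required column(s): {missing}")
    for col in ("ESR1_status", "TP53_status"):
        vals = df[col].astype("string")
        bad = ~(vals.isin(GENE_STATUSES) | vals.isna())
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"row {row}: {col}={df[col].iloc[row]!r} outside alphabet {GENE_STATUSES}"
            )
    if "TP53_class" in df.columns:
        vals = df["TP53_class"].astype("string")
        bad = ~(vals.isin(MUTATION_CLASSES) | vals.isna() | (vals == ""))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"row {row}: TP53_class={df['TP53_class'].iloc[row]!r} "
                f"outside alphabet {MUTATION_CLASSES}"
            )
    if "TP53_vaf" in df.columns:
        vaf = pd.to_numeric(df["TP53_vaf"], errors="coerce")
        present = df["TP53_vaf"].notna() & (df["TP53_vaf"].astype(str) != "")
        bad = present & (vaf.isna() | (vaf < 0) | (vaf > 1))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"row {row}: TP53_vaf={df['TP53_vaf'].iloc[row]!r} not in [0, 1]")
    dup = df.duplicated(subset=["cohort", "sample_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"row {row}: duplicate (cohort, sample_id) = "
            f"({df['cohort'].iloc[row]!r}, {df['sample_id'].iloc[row]!r})"
        )
    if "er_pathology" in df.columns:
        vals = df["er_pathology"].astype("string")
        bad = ~(vals.isin(ER_PATHOLOGY_LEVELS) | vals.isna() | (vals == ""))
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"row {row}: er_pathology={df['er_pathology'].iloc[row]!r} "
                f"outside {ER_PATHOLOGY_LEVELS}"
            )
    return df


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV; unknown covariate columns are preserved verbatim."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    if "TP53_vaf" in df.columns:
        df["TP53_vaf"] = pd.to_numeric(df["TP53_vaf"], errors="coerce")
    validate_genotypes(df)
    logger.info("read %d genotype records from %s", len(df), path)
    return df


def write_genotypes(df: pd.DataFrame, path: str | Path) -> None:
    validate_genotypes(df)
    df.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a feature x sample TSV (first column feature id, header samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: empty matrix")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature id(s) {dup[:5]}")
    nonnum = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(nonnum):
        raise FormatError(f"{path}: non-numeric cells in column(s) {nonnum.tolist()[:5]}")
    logger.info("read %d x %d matrix from %s", df.shape[0], df.shape[1], path)
    return ExpressionMatrix(df, scale)


def write_matrix(matrix: ExpressionMatrix, path: str | Path, feature_col: str = "feature") -> None:
    matrix.data.rename_axis(feature_col).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED / gene models / chrom sizes
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, source: str | None = None) -> PeakSet:
    """Read BED3+; extra columns (name, score, strand, ...) are ignored."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start {start} >= end {end}")
            rows.append((chrom, start, end))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return PeakSet(df, source=source or Path(path).stem)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    peaks.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_gene_model(path: str | Path) -> GeneModel:
    """Read a gene-model TSV (gene, chrom, tss, strand) with 1-based TSS."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: gene model missing column(s) {sorted(missing)}")
    df = df.copy()
    df["tss"] = df["tss"].astype(np.int64) - 1  # 1-based point -> 0-based
    if (df["tss"] < 0).any():
        raise FormatError(f"{path}: TSS coordinate < 1")
    return GeneModel(df)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    out = model.genes.copy()
    out["tss"] = out["tss"].astype(np.int64) + 1  # back to 1-based on disk
    out.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected two columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT (name, description, members...) -> {name: members}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            name, members = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


# ---------------------------------------------------------------------------
# FASTA / YAML
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh)
    if not isinstance(out, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    return out
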