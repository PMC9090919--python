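"""Core in-memory containers shared across the pipeline.

Genotype tables are plain :class:`pandas.DataFrame` objects validated by
:func:`mutexome.io.validate_genotypes`; the light wrappers below carry the
extra state (scale tags, interval conventions, provenance) that a bare frame
cannot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: Allowed scale tags for an expression matrix. Scoring operations require a
#: log-scale tag; raw counts are only accepted by the normalization layer.
SCALES = ("raw_counts", "cpm", "log2cpm1", "log2tpm1", "log_intensity")

LOG_SCALES = ("log2cpm1", "log2tpm1", "log_intensity")

GENE_STATUSES = ("WT", "Mut")
MUTATION_CLASSES = ("missense", "nonsense", "splice", "indel", "other")


@dataclass
class ExpressionMatrix:
    """Features x samples real matrix with an explicit scale tag.

    Parameters
    ----------
    data
        Frame indexed by unique feature ids with unique sample-id columns.
    scale
        One of :data:`SCALES`; set before any scoring operation.
    """

    data: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale tag {self.scale!r}; expected one of {SCALES}")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups[:5]}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if self.scale == "raw_counts" and (self.data.to_numpy() < 0).any():
            raise ValueError("raw_counts matrix contains negative entries")

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def row(self, feature: str) -> pd.Series:
        if feature not in self.data.index:
            raise KeyError(f"feature {feature!r} not in matrix")
        return self.data.loc[feature]


@dataclass
class PeakSet:
    """Genomic intervals, 0-based half-open, with a source id."""

    intervals: pd.DataFrame  # columns chrom, start, end
    source: str = "peaks"

    def __post_init__(self) -> None:
        df = self.intervals
        missing = {"chrom", "start", "end"} - set(df.columns)
        if missing:
            raise ValueError(f"peak table missing columns: {sorted(missing)}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][:5].tolist()
            raise ValueError(f"start >= end for peak rows {bad}")

    def __len__(self) -> int:
        return len(self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Return per-chromosome (n, 2) arrays of [start, end)."""
        out: dict[str, np.ndarray] = {}
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            arr = grp[["start", "end"]].to_numpy(dtype=np.int64)
            out[str(chrom)] = arr[np.argsort(arr[:, 0], kind="stable")]
        return out


@dataclass
class GeneModel:
    """Gene id, chromosome, strand-aware TSS (stored 0-based) per gene."""

    genes: pd.DataFrame  # columns gene, chrom, tss, strand; tss 0-based

    def __post_init__(self) -> None:
        df = self.genes
        missing = {"gene", "chrom", "tss", "strand"} - set(df.columns)
        if missing:
            raise ValueError(f"gene model missing columns: {sorted(missing)}")
        if df["gene"].duplicated().any():
            raise ValueError("duplicate gene ids in gene model")
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(f"invalid strand for genes {df.loc[bad_strand, 'gene'][:5].tolist()}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureSet:
    """A named gene list plus a record of how it was derived."""

    name: str
    members: tuple[str, ...]
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"signature {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"signature {self.name!r} has duplicate members")
        self.members = tuple(str(m) for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)
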