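"""Synthetic cohorts with planted statistical structure.

Every input the pipeline consumes can be generated here with known ground
truth: two-gene genotype tables with an exactly controlled co-occurrence
odds ratio, paired expression cohorts with a planted down-shift of ESR1 and
a subset of a 200-gene estrogen-response universe in TP53-mutant samples,
miRNA matrices with planted anti-ESR1 correlations and matching seed
sequences, peak sets with a controlled overlap fraction, and ER-labelled
reference cohorts built from expression through a known cutoff plus label
noise. Generation is bit-reproducible given the config seed; each generator
draws from its own independent stream derived from that seed.

Defaults mirror the study conditions: TP53 and ESR1 mutation prevalences of
30%, a planted odds ratio of 0.2 (strong exclusivity), a 70-gene planted
signature inside the 200-gene universe, and an ER cutoff of 5.6 with 4.5%
pathology label noise (expected concordance 95.5%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GeneModel, PeakSet, SignatureSet

UNIVERSE_SIZE = 200
UNIVERSE_PREFIX = "E2G"

# independent RNG stream ids per generator
_STREAM_GENOTYPES = 1
_STREAM_EXPRESSION = 2
_STREAM_MIRNA = 3
_STREAM_REGULOME = 4
_STREAM_ER = 5
_STREAM_COUNTS = 6
_STREAM_MIRNA_TARGETS = 7


class ParameterError(ValueError):
    """Requested generator parameters admit no valid joint distribution."""


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_samples_per_cohort: int = 500
    p_tp53: float = 0.30
    p_esr1: float = 0.30
    target_or: float = 0.2
    n_genes: int = 5000
    signature_size: int = 70
    effect_delta: float = 1.5
    noise_sd: float = 1.0
    er_cutoff_true: float = 5.6
    label_noise: float = 0.045
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_cohort <= 0:
            raise ParameterError("n_samples_per_cohort must be positive")
        for name in ("p_tp53", "p_esr1", "label_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.target_or < 0:
            raise ParameterError(f"target_or={self.target_or} must be >= 0")
        if self.n_genes < UNIVERSE_SIZE:
            raise ParameterError(f"n_genes must be >= {UNIVERSE_SIZE}")
        if not 0 < self.signature_size <= min(self.n_genes, UNIVERSE_SIZE):
            raise ParameterError("signature_size must be in (0, 200]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def solve_cell_probabilities(
    p_esr1: float, p_tp53: float, target_or: float
) -> tuple[float, float, float, float]:
    """2x2 cell probabilities (p00, p10, p01, p11) matching marginals and OR.

    p11 is the dual-mutant cell; it solves the quadratic
    (OR-1)*p11^2 - [1 + (p1+p2)(OR-1)]*p11 + OR*p1*p2 = 0 and the root in
    [0, min(p1, p2)] is taken. Raises :class:`ParameterError` when no valid
    solution exists for the requested (marginals, OR) triple.
    """
    p1, p2, theta = p_esr1, p_tp53, target_or
    if theta == 0.0:
        p11 = 0.0
    elif theta == 1.0:
        p11 = p1 * p2
    else:
        s = 1.0 + (p1 + p2) * (theta - 1.0)
        disc = s * s - 4.0 * theta * (theta - 1.0) * p1 * p2
        if disc < 0:
            raise ParameterError(
                f"no real solution for (p_esr1={p1}, p_tp53={p2}, target_or={theta})"
            )
        p11 = (s - math.sqrt(disc)) / (2.0 * (theta - 1.0))
    cells = (1.0 - p1 - p2 + p11, p1 - p11, p2 - p11, p11)
    if any(c < -1e-12 for c in cells):
        raise ParameterError(
            f"infeasible cells for (p_esr1={p1}, p_tp53={p2}, target_or={theta}): {cells}"
        )
    return tuple(max(c, 0.0) for c in cells)  # type: ignore[return-value]


@dataclass(frozen=True)
class CovariateSchema:
    """Categorical covariate with optional distinct dual-mutant distribution."""

    name: str
    levels: tuple[str, ...]
    probs: tuple[float, ...]
    dual_probs: tuple[float, ...] | None = None


DEFAULT_COVARIATES = (
    CovariateSchema("histology", ("ductal", "lobular", "other"), (0.70, 0.20, 0.10)),
    # dual mutants carry a planted liver-metastasis excess
    CovariateSchema(
        "met_site", ("liver", "bone", "lung", "other"),
        (0.25, 0.35, 0.20, 0.20), dual_probs=(0.55, 0.20, 0.10, 0.15),
    ),
)

# TP53 mutation class mix; dual mutants planted with missense/splice excess
_TP53_CLASSES = ("missense", "nonsense", "splice", "indel", "other")
_TP53_CLASS_P = (0.60, 0.15, 0.10, 0.10, 0.05)
_TP53_CLASS_P_DUAL = (0.70, 0.05, 0.20, 0.04, 0.01)

_MISSENSE_VARIANTS = ("R175H", "R248Q", "R273H", "R282W", "G245S", "Y220C", "R249S", "H179R")
_ESR1_MUTATIONS = ("D538G", "Y537S", "E380Q", "other")
_ESR1_MUTATION_P = (0.40, 0.30, 0.10, 0.20)

#: Gain-of-function catalog used by the synthetic cohorts (hotspot missense).
GOF_CATALOG = frozenset({"R175H", "R248Q", "R273H", "R282W"})


def gen_genotypes(
    cfg: SynthConfig,
    covariates: tuple[CovariateSchema, ...] = DEFAULT_COVARIATES,
    cohort: str = "synthetic",
) -> pd.DataFrame:
    """Two-gene genotype table with the planted co-occurrence odds ratio.

    VAF is Beta(2, 5) for single TP53 mutants and Beta(5, 2) for dual
    mutants (a planted upward shift); covariates are drawn per schema, with
    the dual-mutant distribution where one is declared.
    """
    rng = cfg.rng(_STREAM_GENOTYPES)
    n = cfg.n_samples_per_cohort
    cells = solve_cell_probabilities(cfg.p_esr1, cfg.p_tp53, cfg.target_or)
    # cell order: (00) both WT, (10) ESR1-only, (01) TP53-only, (11) dual
    cell_idx = rng.choice(4, size=n, p=cells)
    esr1_mut = np.isin(cell_idx, (1, 3))
    tp53_mut = np.isin(cell_idx, (2, 3))
    dual = esr1_mut & tp53_mut

    df = pd.DataFrame({
        "sample_id": [f"S{i:05d}" for i in range(n)],
        "cohort": cohort,
        "ESR1_status": np.where(esr1_mut, "Mut", "WT"),
        "TP53_status": np.where(tp53_mut, "Mut", "WT"),
    })

    tp53_class = np.full(n, "", dtype=object)
    idx_single = np.flatnonzero(tp53_mut & ~dual)
    idx_dual = np.flatnonzero(dual)
    tp53_class[idx_single] = rng.choice(_TP53_CLASSES, size=len(idx_single), p=_TP53_CLASS_P)
    tp53_class[idx_dual] = rng.choice(_TP53_CLASSES, size=len(idx_dual), p=_TP53_CLASS_P_DUAL)
    df["TP53_class"] = tp53_class

    protein_change = np.full(n, "", dtype=object)
    is_missense = tp53_class == "missense"
    protein_change[is_missense] = rng.choice(_MISSENSE_VARIANTS, size=int(is_missense.sum()))
    df["protein_change"] = protein_change

    vaf = np.full(n, np.nan)
    vaf[idx_single] = rng.beta(2, 5, size=len(idx_single))
    vaf[idx_dual] = rng.beta(5, 2, size=len(idx_dual))
    df["TP53_vaf"] = vaf

    esr1_variant = np.full(n, "", dtype=object)
    idx_esr1 = np.flatnonzero(esr1_mut)
    esr1_variant[idx_esr1] = rng.choice(_ESR1_MUTATIONS, size=len(idx_esr1), p=_ESR1_MUTATION_P)
    df["ESR1_mutation"] = esr1_variant

    for schema in covariates:
        vals = rng.choice(schema.levels, size=n, p=schema.probs)
        if schema.dual_probs is not None and len(idx_dual):
            vals[idx_dual] = rng.choice(schema.levels, size=len(idx_dual), p=schema.dual_probs)
        df[schema.name] = vals

    df["er_pathology"] = "pos"  # cohorts are pre-selected ER+
    return df


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gene_names(cfg: SynthConfig) -> list[str]:
    universe = [f"{UNIVERSE_PREFIX}{i:04d}" for i in range(1, UNIVERSE_SIZE + 1)]
    background = [f"BG{i:04d}" for i in range(1, cfg.n_genes - UNIVERSE_SIZE + 1)]
    return ["ESR1", *universe, *background]


def universe_signature(cfg: SynthConfig) -> SignatureSet:
    """The 200-gene estrogen-response derivation universe."""
    return SignatureSet(
        "EstrogenResponseEarly",
        tuple(f"{UNIVERSE_PREFIX}{i:04d}" for i in range(1, UNIVERSE_SIZE + 1)),
        {"source": "synthetic universe"},
    )


def gen_expression(
    cfg: SynthConfig, genotypes: pd.DataFrame
) -> tuple[ExpressionMatrix, SignatureSet]:
    """Log-scale genes x samples matrix with the planted TP53-mutant shift.

    ESR1 and the first ``signature_size`` universe genes are shifted down by
    ``effect_delta`` in TP53-mutant samples; all other genes carry no signal.
    Returns the matrix and the planted gene set as ground truth.
    """
    rng = cfg.rng(_STREAM_EXPRESSION)
    samples = genotypes["sample_id"].tolist()
    names = gene_names(cfg)
    n_feat, n_samp = len(names), len(samples)
    baseline = rng.normal(7.0, 1.5, size=n_feat)
    baseline[0] = 8.0  # ESR1
    x = baseline[:, None] + rng.normal(0.0, cfg.noise_sd, size=(n_feat, n_samp))

    planted = [f"{UNIVERSE_PREFIX}{i:04d}" for i in range(1, cfg.signature_size + 1)]
    shift_rows = np.isin(names, ["ESR1", *planted])
    tp53_mut = (genotypes["TP53_status"] == "Mut").to_numpy()
    x[np.ix_(shift_rows, tp53_mut)] -= cfg.effect_delta

    expr = ExpressionMatrix(pd.DataFrame(x, index=names, columns=samples), "log2cpm1")
    sig = SignatureSet(
        "planted-TP53-ER", tuple(planted),
        {"source": "synthetic ground truth", "effect_delta": cfg.effect_delta},
    )
    return expr, sig


def expression_to_counts(
    cfg: SynthConfig, expr: ExpressionMatrix, depth: float = 1e6
) -> ExpressionMatrix:
    """Derive a raw-count matrix by exponentiation and a Poisson draw."""
    rng = cfg.rng(_STREAM_COUNTS)
    intensity = np.maximum(2.0 ** expr.data.to_numpy() - 1.0, 0.0)
    lam = intensity / intensity.sum(axis=0, keepdims=True) * depth
    counts = rng.poisson(lam)
    return ExpressionMatrix(
        pd.DataFrame(counts, index=expr.features, columns=expr.samples), "raw_counts"
    )


# ---------------------------------------------------------------------------
# ER-labelled reference cohort
# ---------------------------------------------------------------------------

def gen_er_cohort(cfg: SynthConfig, n_samples: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """ESR1 values and noisy pathology labels around the planted cutoff.

    Values are a two-component Gaussian mixture straddling
    ``er_cutoff_true``; the noiseless label is value >= cutoff, then each
    label is flipped independently with probability ``label_noise``.
    """
    rng = cfg.rng(_STREAM_ER)
    n = n_samples or cfg.n_samples_per_cohort
    is_high = rng.random(n) < 0.60
    values = np.where(
        is_high,
        rng.normal(cfg.er_cutoff_true + 1.8, 1.2, size=n),
        rng.normal(cfg.er_cutoff_true - 2.0, 1.2, size=n),
    )
    truth = values >= cfg.er_cutoff_true
    flip = rng.random(n) < cfg.label_noise
    labels = np.where(truth ^ flip, "pos", "neg")
    return values, labels


# ---------------------------------------------------------------------------
# miRNA matrix and sequences
# ---------------------------------------------------------------------------

_DNA = np.array(list("ACGT"))
_RNA = np.array(list("ACGU"))


@dataclass
class MirnaSynthOutput:
    expr: ExpressionMatrix
    planted_ids: list[str]
    mature_seqs: dict[str, str]
    transcript: str


def gen_mirna(
    cfg: SynthConfig,
    expression: ExpressionMatrix,
    n_mirna: int = 60,
    n_planted: int = 12,
    transcript_length: int = 2000,
    mature_length: int = 22,
) -> MirnaSynthOutput:
    """miRNA matrix, mature sequences and an ESR1 transcript with planted sites.

    Exactly the planted miRNAs (i) are negatively correlated with the ESR1
    row of ``expression`` and (ii) carry a seed (positions 2-8) whose reverse
    complement occurs in the generated transcript; decoys satisfy neither.
    """
    from .mirna import seed_sites  # local import to avoid a cycle

    if "ESR1" not in expression.data.index:
        raise ValueError("expression matrix must contain an ESR1 row")
    if not 0 < n_planted < n_mirna:
        raise ParameterError("need 0 < n_planted < n_mirna")
    rng = cfg.rng(_STREAM_MIRNA)
    esr1 = expression.row("ESR1").to_numpy(dtype=float)
    z = (esr1 - esr1.mean()) / esr1.std()
    samples = expression.samples

    transcript = "".join(rng.choice(_DNA, size=transcript_length))
    rc = str.maketrans("ACGT", "TGCA")

    ids, seqs = [], {}
    site_starts = np.linspace(0, transcript_length - 9, n_planted).astype(int)
    for k in range(n_planted):
        mid = f"miR-P{k + 1:03d}"
        site = transcript[site_starts[k] : site_starts[k] + 7]
        seed7 = site.translate(rc)[::-1].replace("T", "U")  # miRNA positions 2-8
        rest = "".join(rng.choice(_RNA, size=mature_length - 8))
        mature = "".join(rng.choice(_RNA)) + seed7 + rest
        ids.append(mid)
        seqs[mid] = mature
    for k in range(n_mirna - n_planted):
        mid = f"miR-D{k + 1:03d}"
        while True:  # resample until the decoy has no seed site at all
            mature = "".join(rng.choice(_RNA, size=mature_length))
            if not seed_sites(mature, transcript):
                break
        ids.append(mid)
        seqs[mid] = mature

    x = np.empty((n_mirna, len(samples)))
    for i, mid in enumerate(ids):
        base = rng.normal(6.0, 0.5)
        noise = rng.normal(0.0, cfg.noise_sd, size=len(samples))
        if mid.startswith("miR-P"):
            x[i] = base - z + noise
        else:
            x[i] = base + noise
    expr = ExpressionMatrix(pd.DataFrame(x, index=ids, columns=samples), "log_intensity")
    return MirnaSynthOutput(expr, ids[:n_planted], seqs, transcript)


def gen_mirna_targets(
    cfg: SynthConfig,
    mirna_ids: list[str],
    genes: list[str],
    per_mirna_fraction: float = 0.05,
) -> pd.DataFrame:
    """Synthetic miRNA -> target-gene table (stand-in for a target database).

    Each miRNA targets an independent random ``per_mirna_fraction`` of the
    gene universe, mimicking the breadth of predicted-target catalogs.
    """
    rng = cfg.rng(_STREAM_MIRNA_TARGETS)
    n_per = max(1, int(round(per_mirna_fraction * len(genes))))
    rows = []
    for mid in mirna_ids:
        for g in rng.choice(genes, size=n_per, replace=False):
            rows.append((mid, g))
    return pd.DataFrame(rows, columns=["mirna_id", "gene"])


# ---------------------------------------------------------------------------
# regulome
# ---------------------------------------------------------------------------

@dataclass
class RegulomeSynthOutput:
    peaks_a: PeakSet
    peaks_b: PeakSet
    gene_model: GeneModel
    chrom_sizes: dict[str, int]
    true_genes: set[str] = field(default_factory=set)  # genes within window of A
    window: int = 100_000


def gen_regulome(
    cfg: SynthConfig,
    n_peaks: int = 2000,
    overlap: float = 0.25,
    n_genes_model: int = 500,
    n_chroms: int = 4,
    chrom_length: int = 60_000_000,
    peak_width: tuple[int, int] = (200, 2000),
    window: int = 100_000,
    gene_ids: list[str] | None = None,
) -> RegulomeSynthOutput:
    """Two peak sets with a controlled A-vs-B overlap fraction plus gene model.

    A fraction ``overlap`` of B peaks is constructed to intersect a distinct
    A peak; the remaining B peaks are rejection-sampled away from A. The
    ground-truth annotation (genes with TSS within ``window`` of any A peak)
    is computed exhaustively at generation time.
    """
    rng = cfg.rng(_STREAM_REGULOME)
    chrom_sizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    chroms = np.array(sorted(chrom_sizes))

    def draw_peaks(n: int) -> pd.DataFrame:
        c = rng.choice(chroms, size=n)
        w = rng.integers(peak_width[0], peak_width[1] + 1, size=n)
        s = rng.integers(0, chrom_length - w + 1)
        return pd.DataFrame({"chrom": c, "start": s, "end": s + w})

    a_df = draw_peaks(n_peaks)
    peaks_a = PeakSet(a_df, source="p53_synth")

    a_by_chrom = {c: g[["start", "end"]].to_numpy() for c, g in a_df.groupby("chrom")}

    def hits_a(chrom: str, start: int, end: int) -> bool:
        arr = a_by_chrom.get(chrom)
        if arr is None:
            return False
        return bool(np.any((arr[:, 0] < end) & (arr[:, 1] > start)))

    n_overlap = int(round(overlap * n_peaks))
    partners = rng.permutation(n_peaks)[:n_overlap]
    rows = []
    for idx in partners:
        chrom, a_s, a_e = a_df.iloc[idx]["chrom"], int(a_df.iloc[idx]["start"]), int(a_df.iloc[idx]["end"])
        w = int(rng.integers(peak_width[0], peak_width[1] + 1))
        lo = max(0, a_s - w + 1)
        hi = min(a_e - 1, chrom_length - w)
        s = int(rng.integers(lo, hi + 1))
        rows.append((chrom, s, s + w))
    n_rest = n_peaks - n_overlap
    while n_rest > 0:
        cand = draw_peaks(1).iloc[0]
        if not hits_a(cand["chrom"], int(cand["start"]), int(cand["end"])):
            rows.append((cand["chrom"], int(cand["start"]), int(cand["end"])))
            n_rest -= 1
    peaks_b = PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), source="er_synth")

    if gene_ids is not None:
        n_genes_model = len(gene_ids)
    genes = pd.DataFrame({
        "gene": gene_ids if gene_ids is not None
        else [f"G{i:05d}" for i in range(1, n_genes_model + 1)],
        "chrom": rng.choice(chroms, size=n_genes_model),
        "tss": rng.integers(window, chrom_length - window, size=n_genes_model),
        "strand": rng.choice(["+", "-"], size=n_genes_model),
    })
    model = GeneModel(genes)

    true_genes: set[str] = set()
    for _, g in genes.iterrows():  # exhaustive all-pairs ground truth
        arr = a_by_chrom.get(g["chrom"])
        if arr is None:
            continue
        t = int(g["tss"])
        dist = np.where(
            (arr[:, 0] <= t) & (t < arr[:, 1]), 0,
            np.minimum(np.abs(arr[:, 0] - t), np.abs(t - (arr[:, 1] - 1))),
        )
        if dist.min() <= window:
            true_genes.add(g["gene"])

    return RegulomeSynthOutput(peaks_a, peaks_b, model, chrom_sizes, true_genes, window)
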