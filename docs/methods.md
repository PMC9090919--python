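# Methods

This note records the statistical procedures implemented in `mutexome`, the
modelling assumptions behind the synthetic-cohort generator, the numerical
conventions, and the design choices made where a published description left
the details open.

## Exclusivity statistics

For a two-gene genotype table the 2×2 contingency is laid out as
`a = n(ESR1 WT, TP53 WT)`, `b = n(ESR1 Mut, TP53 WT)`,
`c = n(ESR1 WT, TP53 Mut)`, `d = n(both Mut)`, with the cross-product odds
ratio `OR = a·d/(b·c)`. An OR below 1 means the dual-mutant cell is depleted
relative to independence — the exclusivity signal.

* **Exact test.** Two-sided Fisher p by minimum-likelihood summation: with
  margins fixed, sum the hypergeometric point probabilities of every table
  whose probability is at most that of the observed table, with a relative
  tolerance of 1e−7 on the comparison (the convention of mainstream exact-
  test implementations, which makes results reproducible across libraries).
  A zero margin makes the table degenerate; p = 1 by convention, logged.
  The point probabilities come from `scipy.stats.hypergeom`; the summation
  rule is implemented here and is verified in the tests against exhaustive
  binomial-coefficient enumeration on every table with N ≤ 30, and against
  `scipy.stats.fisher_exact` as an independent cross-check.
* **Odds-ratio CI.** Woolf (log-normal) intervals:
  `exp(log OR ± z_{0.975}·sqrt(Σ 1/cell))`. If any cell is zero, 0.5 is
  added to all four cells (Haldane–Anscombe) for both the estimate and the
  interval — never for the exact test, which needs the raw counts. Exact
  (conditional) intervals are not implemented. Coverage of the 95% interval
  is verified by simulation: over 2000 synthetic cohorts of n = 500 at a
  planted OR of 0.3, the interval covers the truth 93–97% of the time.
* **Stratified screen.** One contingency per stratum predicate; strata with
  fewer than 2 usable samples are flagged and receive no test. Excluded
  samples (failed filter, missing status) are counted per stratum.
* **Dual-mutant enrichment.** Within TP53-mutant samples, each level of a
  categorical feature is tested in a 2×2 of (dual-mutant vs TP53-only) ×
  (level vs not). Raw p-values are reported alongside Benjamini–Hochberg
  q-values across levels; the published analysis names no correction, so BH
  is the package's conservative default.
* **VAF comparison.** Mann–Whitney U, exact enumeration when both groups
  have ≤ 8 samples, otherwise the normal approximation with continuity and
  tie correction (scipy defaults).

## Synthetic cohorts

The generator is the package's study-condition definition, not a tuning
surface. Given marginal mutation prevalences `p_esr1`, `p_tp53` and a target
odds ratio θ, the dual-mutant cell probability solves the quadratic
`(θ−1)·p11² − [1 + (p1+p2)(θ−1)]·p11 + θ·p1·p2 = 0` (root in
`[0, min(p1, p2)]`; θ = 1 gives independence, θ = 0 empties the cell), so
the planted exclusivity is exact in distribution. Infeasible triples raise a
parameter error naming them.

Defaults: prevalences 0.30 for both genes (both mutations occur in roughly
30% of the relevant ER+ populations), planted OR 0.2 (strong exclusivity),
cohorts of 500 samples. TP53 VAF is Beta(2, 5) for single mutants and
Beta(5, 2) for dual mutants — bounded, skewed, and shifted upward in dual
mutants so the VAF comparison has a planted effect. Dual mutants also carry
a planted excess of liver metastases and of missense/splice TP53 classes.

Expression is generated directly on the log2 scale (gene baselines
N(7, 1.5²), per-gene Gaussian noise with sd 1.0); ESR1 and the first 70
genes of a 200-gene estrogen-response universe are shifted by −1.5 in
TP53-mutant samples. The default gene count is 5000 — a transcriptome-scale
subset chosen so the regulome's published >1000-target dataset filter
operates at its real threshold on synthetic data. Raw counts for TMM testing
are derived by exponentiation and a Poisson draw.

The ER reference cohort draws ESR1 values from a two-component Gaussian
mixture straddling the planted cutoff 5.6 log2(CPM+1); pathology labels are
the thresholded values with 4.5% independent flips, so the best achievable
concordance is 95.5% and it is attained at the planted cutoff.

miRNA synthesis plants, for each of 12 regulator miRNAs, (i) expression
equal to the negated standardized ESR1 profile plus noise and (ii) a mature
sequence whose positions 2–8 are the reverse complement of a 7-mer in the
generated ESR1 transcript; decoy miRNAs are resampled until they carry no
seed site at all. The regulome generator constructs a controlled fraction of
query peaks with an overlapping partner peak and rejection-samples the rest
away, so the realized overlap equals the request to within ±0.02; the
ground-truth ±100 kb annotation is computed exhaustively at generation time.

Each generator draws from an independent RNG stream derived from the config
seed; identical configs give byte-identical outputs.

**What the generator does not emulate:** linkage between covariates and
expression beyond the planted shift, over-dispersed counts, batch effects,
probe-level artifacts, miRNA target-site accessibility, or realistic peak
clustering (peaks are uniform within chromosomes). Passing tests therefore
demonstrate correctness of the statistical machinery under the planted
model, not robustness to every failure mode of real cohorts.

## ER calibration

Cutoffs run in steps of 0.1 over the closed interval between the first and
third quartiles of the target cohort's ESR1 values (quartiles rounded to one
decimal so the grid is aligned). A reference sample is predicted positive
iff its value is ≥ the cutoff (the boundary assignment is unobservable at
grid resolution; ≥ makes it deterministic); concordance is the fraction of
predictions matching pathology, with missing labels excluded from the
denominator and counted. Ties on concordance go to the smallest cutoff. The
reference cohort is always passed explicitly — no accession is hard-coded.

## TMM and probe collapse

TMM follows the published trimmed-mean-of-M-values description rather than
any specific binary: reference = sample whose upper-quartile composition is
closest to the mean; per sample, gene-wise log-ratios M and abundances A
against the reference over genes expressed in both; 30% of each M tail and
5% of each A tail trimmed by rank; factor = 2^(precision-weighted mean of
the remaining M), with inverse-binomial weights; factors renormalized to
multiply to 1 (identity holds to 1e−12 in tests). Probe collapse keeps, per
gene, the probe with the largest inter-quartile range across samples, ties
broken by lexicographically smallest probe id.

## Enrichment scoring

The single-sample scorer follows the GSVA design for continuous log-scale
data: each gene's values are replaced by their empirical CDF across samples;
per sample, genes are ranked by the transformed value (ties averaged for the
rank statistic, exact ordering ties broken by lexicographic gene id so the
score is invariant to row order); a random walk down the ranked list adds
normalized `|(p+1)/2 − rank|^τ` weights (τ = 1) at set members and subtracts
`1/(p−k)` at non-members; the score is the signed sum of the maximum
positive and maximum negative deviation. Bit-compatibility with any external
implementation is a non-goal — the contract is the invariances: zero-mean
under a permutation null, strict response to coordinated shifts, and
invariance to gene order and to strictly monotone per-gene transforms.
Note that the across-sample ECDF makes the score relative: a constant shift
of a gene across *all* samples is invisible by design.

## Differential screen and signature derivation

Per cohort, each universe gene is tested between mutant and WT groups with
a two-sided Mann–Whitney (the analysis chain's pervasive nonparametric
test); BH is computed over exactly the universe (m = |universe| = 200), not
transcriptome-wide. Direction is the sign of the median difference for genes
with q < 0.01, else "unchanged". The TP53-ER signature is the intersection
of "down" calls across the two cohorts; the Non-TP53-ER signature the
intersection of "unchanged" calls; the two are disjoint by construction and
carry full derivation provenance. Per-patient trajectory scoring orders each
patient's samples primary-first and emits per-lesion deltas; scoring is
joint across patients, recorded in provenance.

## p53 functional classes

LOFS is the arithmetic mean of the available per-promoter transactivation
percentages (tables may carry 7 or 8 promoter columns; missing values are
skipped and counted). The printed class rule leaves LOFS = 1 and LOFS = 10
unassigned; both boundaries close into "medium" ([1, 10]), preserving the
strict inequalities of "weak" and "strong". Non-missense variants are
unclassified. GoF status is an exact catalog lookup after normalization
(strip `p.`, uppercase, trim). IHC percentages are rounded half-up before
the integer band rule, so the partition of [0, 100] has no gaps.

## miRNA screen

"Anti-ESR1 match" is operationalized as the canonical seed-site classes on
the transcript sense strand: 7mer-m8 (reverse complement of miRNA positions
2–8), 7mer-A1 (reverse complement of positions 2–7 followed by an A), and
8mer (both at one locus, reported once as an 8mer, suppressing its
constituent 7mer calls). The full transcript is scanned, not only the 3'
UTR; transcripts may be given in DNA or RNA alphabet. Selection is a strict
Pearson r < 0 against ESR1 expression with no p-value filter, exactly as the
screen rule states; Spearman is available behind a flag. Zero-variance
miRNAs stay in the candidate table, flagged, and are never selected.

## Regulome

Gene-to-peak annotation anchors on the strand-aware TSS and uses a hard
±100 kb window to the nearest peak boundary (TSS inside a peak ⇒ distance
0); a hard window, rather than a decayed regulatory-potential score, is the
deterministic and oracle-testable reading of the rule (a gene-body anchor is
available via the stored coordinates but undocumented). Datasets with
strictly more than 1000 annotated genes are retained and their union taken.
Overlap is asymmetric — the fraction of query peaks sharing ≥ 1 bp with any
subject peak, each query peak counted once. The null relocates every query
peak uniformly within its own chromosome, preserving per-chromosome counts
and the width multiset (a conservative null respecting chromosomal peak
density; genome-wide relocation was considered and rejected as
anti-conservative). Significance pools the randomized overlapping /
non-overlapping counts into one 2×2 exact test — a Fisher test needs integer
counts, and pooling is the only construction consistent with comparing
"observed vs randomized regions"; the per-set random fractions also give an
empirical p `(1 + #{random ≥ observed}) / (n_sets + 1)` whose null
uniformity is verified by a KS test in the acceptance suite.

The dual-mechanism report partitions signature genes into
{both, chip-only, miRNA-only, neither}; union and both percentages use the
signature size as denominator and are rounded to one decimal. miRNA target
genes are taken from a user-supplied (or synthesized) miRNA→gene table —
target-database versions are external inputs, never bundled.

## Pipeline

Stages communicate only through files in the output directory (plain TSV /
JSON / GMT / BED); each run writes a summary JSON of headline quantities and
a manifest with the full configuration and sha256 checksums of every output.
A failing stage is recorded in the summary and does not corrupt completed
stages. Runs are deterministic given (config, seed); derived cohort seeds
are fixed offsets of the config seed.

## Problem sizes

Simulation-based checks use cohorts of 300–6000 samples, 200–5000 genes,
60 miRNAs, and 200–2000 peaks over 4–10 synthetic chromosomes of 5–80 Mb;
coverage and calibration checks use 100–2000 replicates. These sizes give
stable pass/fail behaviour for the planted effects while keeping the full
suite fast on a single CPU.

## Known limitations

* Exact (conditional) odds-ratio intervals and mid-p variants are not
  implemented; Woolf intervals can be anti-conservative at very small counts
  despite the continuity correction.
* The enrichment scorer implements one variant (ECDF transform, τ = 1,
  signed max-deviation score); Gaussian-kernel CDF estimation and the
  alternative max-deviation score are not exposed.
* The pipeline's miRNA target table and GoF catalog are synthetic stand-ins
  shaped like their real counterparts (target databases, curated mutation
  lists), not reproductions of them.
* Multi-gene exclusivity (beyond one gene pair) and survival analysis are
  out of scope.
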