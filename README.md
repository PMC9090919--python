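# mutexome

Statistical toolkit for dissecting the **mutual exclusivity of *ESR1* and
*TP53* mutations** in estrogen-receptor-positive (ER+) metastatic breast
cancer. Both genes are frequently mutated in ER+ disease — *TP53* early, as
a founder event, and *ESR1* late, under endocrine-therapy pressure — yet
tumors carrying both mutations are rare. `mutexome` implements the full
inference chain used to quantify and explain that observation, and a
synthetic-cohort generator with planted effects so every step is testable
without any external download.

The package is aimed at cancer-genomics analysts who want the individual
statistical building blocks as a library (the `examples/` scripts are the
tour) or the whole chain as a pipeline (`mutexome run`).

## What it computes

* **Exclusivity statistics** — for a two-gene genotype table, the 2×2
  contingency table with odds ratio `OR = a·d/(b·c)` (OR < 1 ⇒ exclusivity
  trend), a Woolf 95% CI on Haldane–Anscombe-corrected counts, and a
  two-sided Fisher exact p computed by minimum-likelihood summation over the
  fixed-margins hypergeometric family; stratified subgroup screens,
  significance-vs-size correlation, dual-mutant feature enrichment
  (BH-corrected) and a VAF comparison (Mann–Whitney U).
* **Expression utilities** — TMM scaling factors, log2(CPM+1), probe→gene
  collapse by maximal IQR, and ER-status calibration: scan cutoffs in 0.1
  steps between the target cohort's ESR1 quartiles and keep the cutoff with
  the highest concordance to pathology labels.
* **Signature derivation and scoring** — per-cohort Mann–Whitney screens
  over a 200-gene estrogen-response universe with BH FDR < 0.01, cross-cohort
  intersection into a "TP53-ER" (consistently down in *TP53*-mutant tumors)
  and a "Non-TP53-ER" (consistently unchanged) signature, and a GSVA-style
  single-sample enrichment score (ECDF transform, rank-weighted random walk,
  signed max-deviation score).
* **p53 functional classes** — loss-of-function score (mean residual
  transactivation across canonical target promoters; strong < 1 %,
  medium 1–10 %, weak > 10 %), gain-of-function catalog lookup, and the
  immunohistochemistry interpretation rule (0–15 % null-aberrant,
  16–79 % wildtype, 80–100 % positive-aberrant).
* **Anti-ESR1 miRNA screen** — canonical seed sites (8mer, 7mer-m8,
  7mer-A1) of mature miRNAs on the ESR1 transcript, strict negative-Pearson
  selection, and set-level abundance scoring.
* **Regulome annotation** — genes within ±100 kb of peaks (strand-aware
  TSS), dataset filtering at > 1000 targets with union, asymmetric peak
  overlap fractions, a randomized-region null (peaks relocated uniformly
  within their chromosome, widths preserved) with pooled exact test and
  empirical p, and the four-way dual-mechanism partition of signature genes.

## Worked example

```bash
python examples/01_mutual_exclusivity.py
```

prints, for a 2000-sample synthetic cohort with a planted odds ratio of 0.2:

```
2x2 counts: bothWT=860  ESR1only=507  TP53only=569  dual=64
odds ratio 0.191 (95% CI 0.144-0.253), Fisher p = 1.09e-39
  histology=ductal       n=1436  OR=0.190 p=3.98e-29
  histology=lobular      n=369   OR=0.235 p=8.08e-07
  histology=other        n=195   OR=0.132 p=3.30e-06
log10(p) vs stratum size: Pearson r = -0.99
```

The global OR of 0.19 recovers the planted exclusivity (only 64 of 2000
tumors carry both mutations, far fewer than expected under independence);
the effect persists in every histology stratum, and the p-values shrink with
stratum size exactly as a fixed effect should. The other examples walk
through ER-cutoff calibration (chooses 5.6 log2(CPM+1) at 95% concordance),
signature derivation (recovers the planted 70-gene set with no false
positives), the miRNA screen (12/12 planted regulators selected) and the
regulome analysis (25% planted peak overlap vs 0.8% in the randomized null).

A full pipeline run with one report bundle:

```bash
mutexome run --seed 1 --outdir out/
```

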