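"""Generator contracts: planted odds ratios, shifts, sequences and peaks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mutexome import (
    SynthConfig,
    gen_expression,
    gen_genotypes,
    gen_regulome,
    solve_cell_probabilities,
)
from mutexome.synth import ParameterError, gen_er_cohort, gen_mirna


def _empirical_or(table: pd.DataFrame) -> float:
    e = (table["ESR1_status"] == "Mut").to_numpy()
    t = (table["TP53_status"] == "Mut").to_numpy()
    a = (~e & ~t).sum()
    b = (e & ~t).sum()
    c = (~e & t).sum()
    d = (e & t).sum()
    return (a * d) / (b * c)


@pytest.mark.parametrize("target", [0.1, 0.5, 1.0, 2.0, 10.0])
def test_or_solver_recovers_target_at_large_n(target):
    cells = solve_cell_probabilities(0.3, 0.3, target)
    assert pytest.approx(sum(cells), abs=1e-12) == 1.0
    cfg = SynthConfig(n_samples_per_cohort=100_000, target_or=target, seed=5)
    table = gen_genotypes(cfg)
    assert _empirical_or(table) == pytest.approx(target, rel=0.10)


def test_or_one_means_independence():
    cfg = SynthConfig(n_samples_per_cohort=100_000, target_or=1.0, seed=2)
    assert 0.9 <= _empirical_or(gen_genotypes(cfg)) <= 1.1


def test_or_zero_empties_dual_cell():
    cfg = SynthConfig(n_samples_per_cohort=20_000, target_or=0.0, seed=3)
    table = gen_genotypes(cfg)
    dual = (table["ESR1_status"] == "Mut") & (table["TP53_status"] == "Mut")
    assert int(dual.sum()) == 0


def test_infeasible_marginals_raise():
    with pytest.raises(ParameterError):
        solve_cell_probabilities(0.7, 0.7, 0.0)  # p00 would be negative
    with pytest.raises(ParameterError):
        SynthConfig(p_tp53=1.5)


def test_generation_is_deterministic(small_cfg):
    pd.testing.assert_frame_equal(gen_genotypes(small_cfg), gen_genotypes(small_cfg))
    e1, s1 = gen_expression(small_cfg, gen_genotypes(small_cfg))
    e2, s2 = gen_expression(small_cfg, gen_genotypes(small_cfg))
    pd.testing.assert_frame_equal(e1.data, e2.data)
    assert s1.members == s2.members


def test_vaf_shift_between_single_and_dual_mutants():
    cfg = SynthConfig(n_samples_per_cohort=5000, seed=4)
    table = gen_genotypes(cfg)
    tp53 = table[table["TP53_status"] == "Mut"]
    dual = tp53["ESR1_status"] == "Mut"
    # Beta(5,2) dual vs Beta(2,5) single: planted upward shift
    assert tp53.loc[dual, "TP53_vaf"].median() > tp53.loc[~dual, "TP53_vaf"].median()


def test_null_expression_carries_no_genotype_signal(genotypes, small_cfg):
    cfg = SynthConfig(
        n_samples_per_cohort=small_cfg.n_samples_per_cohort,
        n_genes=small_cfg.n_genes, effect_delta=0.0, seed=21,
    )
    table = gen_genotypes(cfg)
    expr, planted = gen_expression(cfg, table)
    mut = (table["TP53_status"] == "Mut").to_numpy()
    sub = expr.data.loc[list(planted.members)].to_numpy()
    p = stats.mannwhitneyu(sub[:, mut], sub[:, ~mut], axis=1).pvalue
    # null case: planted genes indistinguishable between genotype groups
    assert (p < 0.01).mean() < 0.05


def test_planted_expression_shift_is_detectable():
    cfg = SynthConfig(n_samples_per_cohort=300, n_genes=300,
                      effect_delta=2.0, noise_sd=0.5, seed=6)
    table = gen_genotypes(cfg)
    expr, planted = gen_expression(cfg, table)
    assert len(planted.members) == cfg.signature_size
    mut = (table["TP53_status"] == "Mut").to_numpy()
    sub = expr.data.loc[list(planted.members)].to_numpy()
    p = stats.mannwhitneyu(sub[:, mut], sub[:, ~mut], axis=1).pvalue
    assert (p < 0.01).mean() >= 0.95


def test_mirna_generator_plants_correlations_and_seeds(small_cfg):
    cfg = SynthConfig(n_samples_per_cohort=500, n_genes=300, noise_sd=0.3, seed=8)
    table = gen_genotypes(cfg)
    expr, _ = gen_expression(cfg, table)
    out = gen_mirna(cfg, expr)
    esr1 = expr.row("ESR1").to_numpy()
    rc = str.maketrans("ACGT", "TGCA")
    for mid in out.planted_ids:
        vals = out.expr.data.loc[mid].to_numpy()
        assert stats.pearsonr(vals, esr1).statistic < -0.5
        seed7 = out.mature_seqs[mid][1:8].replace("U", "T")
        assert seed7.translate(rc)[::-1] in out.transcript
    decoys = [m for m in out.expr.features if m not in out.planted_ids]
    rs = [stats.pearsonr(out.expr.data.loc[m].to_numpy(), esr1).statistic for m in decoys]
    assert max(abs(r) for r in rs) < 0.25


def test_regulome_overlap_fraction_and_bounds(small_cfg):
    out = gen_regulome(small_cfg, n_peaks=2000, overlap=0.25)
    from mutexome import overlap_fraction

    _, frac = overlap_fraction(out.peaks_a, out.peaks_b)
    assert abs(frac - 0.25) <= 0.02
    for peaks in (out.peaks_a, out.peaks_b):
        df = peaks.intervals
        assert (df["start"] >= 0).all()
        limits = df["chrom"].map(out.chrom_sizes)
        assert (df["end"] <= limits).all()


def test_regulome_truth_excludes_distant_genes(small_cfg):
    out = gen_regulome(small_cfg, n_peaks=200, n_genes_model=300)
    ann = out.true_genes
    # verify one distant gene by brute force against the window
    arr = out.peaks_a.intervals
    for _, g in out.gene_model.genes.iterrows():
        peaks = arr[arr["chrom"] == g["chrom"]]
        if peaks.empty:
            assert g["gene"] not in ann
            continue
        t = g["tss"]
        inside = (peaks["start"] <= t) & (t < peaks["end"])
        dist = np.where(
            inside, 0,
            np.minimum((peaks["start"] - t).abs(), (t - (peaks["end"] - 1)).abs()),
        )
        assert (g["gene"] in ann) == (dist.min() <= out.window)


def test_er_cohort_labels_follow_cutoff_with_noise():
    cfg = SynthConfig(label_noise=0.0, seed=10)
    values, labels = gen_er_cohort(cfg, 800)
    assert ((values >= cfg.er_cutoff_true) == (labels == "pos")).all()
    noisy_cfg = SynthConfig(label_noise=0.2, seed=10)
    v2, l2 = gen_er_cohort(noisy_cfg, 5000)
    flip_rate = ((v2 >= cfg.er_cutoff_true) != (l2 == "pos")).mean()
    assert flip_rate == pytest.approx(0.2, abs=0.03)
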