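"""Window annotation, peak-overlap arithmetic and the randomized null."""

import numpy as np
import pandas as pd
import pytest

from mutexome import (
    GeneModel,
    PeakSet,
    SignatureSet,
    annotate_genes_near_peaks,
    dual_mechanism_classify,
    filter_union_targets,
    overlap_fraction,
    overlap_significance,
    randomize_regions,
)


def _peaks(rows, source="p"):
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]), source)


def _genes(rows):
    return GeneModel(pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"]))


def test_annotation_window_arithmetic():
    peaks = _peaks([("chr1", 200_000, 200_500)])
    genes = _genes([
        ("near", "chr1", 150_000, "+"),    # 49,500 bp away -> annotated
        ("far", "chr1", 350_000, "+"),     # 149,500 bp away -> not
        ("inside", "chr1", 200_250, "-"),  # inside the peak -> distance 0
        ("edge", "chr1", 100_000, "+"),    # exactly 100 kb -> annotated
        ("offchrom", "chr1", 0, "+"),
    ])
    ann = annotate_genes_near_peaks(peaks, genes)
    assert ann == {"near", "inside", "edge"}


def test_annotation_chromosome_mismatch_errors():
    peaks = _peaks([("chr1", 0, 100)])
    genes = _genes([("g", "1", 50, "+")])  # ensembl-style naming clash
    with pytest.raises(ValueError, match="chromosome"):
        annotate_genes_near_peaks(peaks, genes)


def test_annotation_matches_all_pairs_oracle():
    rng = np.random.default_rng(51)
    n_peaks, n_genes, window = 500, 500, 100_000
    chroms = [f"chr{i}" for i in range(1, 4)]
    starts = rng.integers(0, 5_000_000, n_peaks)
    peaks = _peaks(list(zip(rng.choice(chroms, n_peaks), starts,
                            starts + rng.integers(100, 2000, n_peaks))))
    genes = _genes(list(zip(
        [f"g{i}" for i in range(n_genes)],
        rng.choice(chroms, n_genes),
        rng.integers(0, 5_000_000, n_genes),
        rng.choice(["+", "-"], n_genes),
    )))
    expected = set()
    pv = peaks.intervals
    for _, g in genes.genes.iterrows():
        sub = pv[pv["chrom"] == g["chrom"]]
        t = g["tss"]
        inside = (sub["start"] <= t) & (t < sub["end"])
        dist = np.where(inside, 0, np.minimum(
            (sub["start"] - t).abs(), (t - (sub["end"] - 1)).abs()))
        if len(dist) and dist.min() <= window:
            expected.add(g["gene"])
    assert annotate_genes_near_peaks(peaks, genes, window) == expected


def test_union_filter_is_strict():
    big = {f"g{i}" for i in range(1500)}
    small = {f"g{i}" for i in range(900)}
    res = filter_union_targets({"ds1": big, "ds2": small}, min_targets=1000)
    assert res.retained == ["ds1"] and res.union_genes == big
    same = filter_union_targets({"a": big, "b": big}, min_targets=1000)
    assert same.union_genes == big
    d1 = {f"x{i}" for i in range(1001)}
    d2 = {f"y{i}" for i in range(1001)}
    assert len(filter_union_targets({"a": d1, "b": d2}).union_genes) == 2002
    res = filter_union_targets({"only": small}, min_targets=1000)
    assert res.flag == "empty_union" and res.union_genes == set()


def test_overlap_fraction_half_open_arithmetic():
    a = _peaks([("chr1", 100, 200)])
    touching = _peaks([("chr1", 199, 300)])
    assert overlap_fraction(a, touching) == (1, 1.0)  # shares base 199
    adjacent = _peaks([("chr1", 200, 300)])
    assert overlap_fraction(a, adjacent) == (0, 0.0)  # half-open: no shared base
    containing = _peaks([("chr1", 0, 1000)])
    assert overlap_fraction(a, containing) == (1, 1.0)
    # one A peak touching many B peaks still counts once
    many = _peaks([("chr1", 100, 120), ("chr1", 130, 160), ("chr1", 170, 199)])
    assert overlap_fraction(a, many) == (1, 1.0)
    with pytest.raises(ValueError, match="empty"):
        overlap_fraction(PeakSet(pd.DataFrame(columns=["chrom", "start", "end"])), a)


def test_randomize_preserves_widths_and_is_seeded():
    rng = np.random.default_rng(53)
    starts = rng.integers(0, 900_000, 100)
    a = _peaks(list(zip(["chr1"] * 50 + ["chr2"] * 50, starts,
                        starts + rng.integers(10, 500, 100))))
    sizes = {"chr1": 1_000_000, "chr2": 1_000_000}
    r1 = randomize_regions(a, sizes, 3, seed=9)
    r2 = randomize_regions(a, sizes, 3, seed=9)
    for s1, s2 in zip(r1, r2):
        pd.testing.assert_frame_equal(s1.intervals, s2.intervals)
    for rand in r1:
        for chrom in sizes:
            w_orig = a.intervals.query("chrom == @chrom").eval("end - start")
            w_rand = rand.intervals.query("chrom == @chrom").eval("end - start")
            assert sorted(w_orig) == sorted(w_rand)
        assert (rand.intervals["start"] >= 0).all()
        assert (rand.intervals["end"] <= 1_000_000).all()


def test_random_overlap_matches_coverage_expectation():
    # single chromosome toy: B fixed, A relocated 1000 times
    L = 1_000_000
    wa, n_a = 100, 50
    b = _peaks([("chr1", s, s + 400) for s in range(100_000, 900_000, 80_000)])
    a = _peaks([("chr1", s, s + wa) for s in np.linspace(0, L - wa, n_a).astype(int)])
    expected = sum((400 + wa - 1) / L for _ in range(len(b)))  # per-peak hit prob
    rng_sets = randomize_regions(a, {"chr1": L}, 1000, seed=77)
    fractions = [overlap_fraction(r, b)[1] for r in rng_sets]
    assert np.mean(fractions) == pytest.approx(expected, rel=0.20)


def test_overlap_significance_degenerate_maximum():
    rng = np.random.default_rng(57)
    starts = rng.integers(0, 990_000, 80)
    a = _peaks(list(zip(["chr1"] * 80, starts, starts + 500)))
    res = overlap_significance(a, a, {"chr1": 1_000_000}, n_sets=50, seed=1)
    assert res.overlap_fraction == 1.0
    assert res.p < 1e-6
    assert max(res.random_fractions) < 1.0
    assert res.p_empirical == pytest.approx(1 / 51)


def test_dual_mechanism_published_arithmetic():
    # 70 signature genes, 33 peak-annotated, 48 miRNA-annotated, 24 in both
    sig = SignatureSet("sig", tuple(f"g{i}" for i in range(70)))
    chip = {f"g{i}" for i in range(33)}                      # g0..g32
    mirna = {f"g{i}" for i in range(9, 57)}                  # 48 genes, 24 shared
    rep = dual_mechanism_classify(sig, chip, mirna)
    assert rep.counts() == {"both": 24, "chip_only": 9, "mirna_only": 24, "neither": 13}
    assert rep.union_count == 57
    assert rep.union_pct == 81.4
    assert rep.both_pct == 34.3


def test_dual_mechanism_partition_properties():
    sig = SignatureSet("sig", tuple(f"g{i}" for i in range(40)))
    chip = {f"g{i}" for i in range(0, 10)}
    mirna = {f"g{i}" for i in range(10, 25)}
    rep = dual_mechanism_classify(sig, chip, mirna)
    counts = rep.counts()
    assert sum(counts.values()) == 40
    assert counts["both"] == 0 and rep.union_count == 25  # disjoint sets add
    # inclusion-exclusion
    assert rep.union_count == len(chip) + len(mirna) - counts["both"]
    full = dual_mechanism_classify(sig, set(sig.members), set(sig.members))
    assert full.union_pct == 100.0 and full.both_pct == 100.0
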