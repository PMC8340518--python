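"""Sliding-window ROH detection against direct enumeration."""

import math

import numpy as np
import pytest

from rohkit.genotypes import MISSING
from rohkit.roh import (RohParams, RohSegment, assemble_runs, detect_roh,
                        min_snps_lencz, per_chromosome_counts,
                        summarize_lengths, window_homozygosity)
from conftest import make_dataset, roh_bruteforce


# --- Lencz minimum SNP count ------------------------------------------------

def test_lencz_direct_evaluation():
    # ceil( ln(0.05 / (50,000*100)) / ln(0.7) ) = ceil(51.65...) = 52
    assert min_snps_lencz(0.05, 50_000, 100, 0.30) == 52


def test_lencz_exact_integer_ratio_unchanged():
    # choose mean_het so the ratio is an exact integer: ratio = ln(a)/ln(b) = k
    alpha, n_snp, n_ind = 0.05, 1000, 20
    target = math.log(alpha / (n_snp * n_ind))
    k = 25
    mean_het = 1.0 - math.exp(target / k)
    assert min_snps_lencz(alpha, n_snp, n_ind, mean_het) == k


def test_lencz_rejects_degenerate_heterozygosity():
    with pytest.raises(ValueError):
        min_snps_lencz(0.05, 1000, 10, 0.0)
    with pytest.raises(ValueError):
        min_snps_lencz(0.05, 1000, 10, 1.0)


# --- window proportions -----------------------------------------------------

def test_window_proportions_all_homozygous_and_all_het():
    params = RohParams(window_snps=10)
    hom = np.zeros(40, dtype=np.int8)
    assert np.all(window_homozygosity(hom, params) == 1.0)
    het = np.ones(40, dtype=np.int8)
    assert np.all(window_homozygosity(het, params) == 0.0)


def test_window_proportions_match_enumeration_with_planted_hets():
    g = np.zeros(60, dtype=np.int8)
    g[10] = 1
    g[30] = 1
    params = RohParams(window_snps=15)
    got = window_homozygosity(g, params)
    pos = list(range(0, 60))
    # enumeration oracle on proportions via the shared brute-force helper:
    w = 15
    windows = [(s, s + w) for s in range(60 - w + 1)]
    elig = [sum(1 for x in g[s:e] if x == 1) <= params.max_het_per_window
            for s, e in windows]
    for j in range(60):
        cover = [k for k, (s, e) in enumerate(windows) if s <= j < e]
        expect = sum(elig[k] for k in cover) / len(cover)
        assert got[j] == pytest.approx(expect)


def test_window_shorter_chromosome_uses_single_truncated_window():
    params = RohParams(window_snps=50, max_het_per_window=1)
    g = np.zeros(10, dtype=np.int8)
    g[3] = 1  # one het within the only (truncated) window -> still eligible
    assert np.all(window_homozygosity(g, params) == 1.0)
    g[7] = 1  # two hets -> ineligible
    assert np.all(window_homozygosity(g, params) == 0.0)


# --- run assembly -----------------------------------------------------------

def test_assemble_accepts_dense_long_run():
    n = 100
    pos = np.arange(n) * 20_000 + 1  # 2 Mb span, 20 kb spacing
    prop = np.ones(n)
    segs = assemble_runs(prop, np.zeros(n), pos, RohParams(), min_snps=53)
    assert len(segs) == 1
    assert segs[0].n_snps == 100
    assert segs[0].length_bp == pos[-1] - pos[0]


def test_assemble_rejects_short_span():
    n = 60
    pos = np.arange(n) * 6_000 + 1  # ~354 kb < 500 kb
    segs = assemble_runs(np.ones(n), np.zeros(n), pos, RohParams(), min_snps=10)
    assert segs == []


def test_assemble_splits_at_large_gap_and_retests():
    pos = np.concatenate([np.arange(50) * 20_000,
                          1_600_000 + np.arange(50) * 20_000])  # 620 kb gap
    segs = assemble_runs(np.ones(100), np.zeros(100), pos,
                         RohParams(max_gap_bp=500_000), min_snps=10)
    assert len(segs) == 2
    assert all(s.length_bp == 49 * 20_000 for s in segs)


def test_assemble_density_rule():
    # 12 SNPs spanning 1.1 Mb -> 91.7 kb/SNP, sparser than 1 per 50 kb
    pos = np.linspace(1, 1_100_000, 12).astype(np.int64)
    segs = assemble_runs(np.ones(12), np.zeros(12), pos, RohParams(), min_snps=5)
    assert segs == []
    # 23 SNPs over the same span passes (47.8 kb/SNP)
    pos = np.linspace(1, 1_100_000, 23).astype(np.int64)
    segs = assemble_runs(np.ones(23), np.zeros(23), pos, RohParams(), min_snps=5)
    assert len(segs) == 1


# --- full detection vs oracle -----------------------------------------------

def _random_instance(rng):
    m = int(rng.integers(30, 500))
    n = int(rng.integers(1, 6))
    # mixture of homozygous stretches and noisy regions
    g = rng.choice([0, 1, 2, MISSING], size=(n, m),
                   p=[0.42, 0.12, 0.42, 0.04]).astype(np.int8)
    for i in range(n):  # plant a few long homozygous tracts
        for _ in range(int(rng.integers(0, 3))):
            s = int(rng.integers(0, m))
            e = min(m, s + int(rng.integers(20, 200)))
            g[i, s:e] = rng.choice([0, 2])
    step = int(rng.integers(5_000, 60_000))
    pos = np.cumsum(rng.integers(1, 2 * step, size=m)) + 1
    return g, pos


@pytest.mark.parametrize("seed", range(8))
def test_detect_roh_equals_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    params = RohParams(window_snps=20, min_snps=15)
    for _ in range(6):
        g, pos = _random_instance(rng)
        ds = make_dataset(g, pos)
        got = [(s.sample_id, s.start_bp, s.end_bp, s.n_snps)
               for s in detect_roh(ds, params)]
        expect = []
        for i in range(g.shape[0]):
            for st, en, n in roh_bruteforce(
                    g[i], pos, window=20, max_het=1, max_missing=1,
                    threshold=0.05, max_gap=500_000, min_density=50_000,
                    min_length=500_000, min_snps=15):
                expect.append((f"s{i}", st, en, n))
        assert sorted(got) == sorted(expect)


def test_detect_roh_segments_never_overlap_within_sample():
    rng = np.random.default_rng(99)
    g, pos = _random_instance(rng)
    ds = make_dataset(g, pos)
    segs = detect_roh(ds, RohParams(window_snps=20, min_snps=10))
    by_sample = {}
    for s in segs:
        by_sample.setdefault((s.sample_id, s.chromosome), []).append(s)
    for lst in by_sample.values():
        lst.sort(key=lambda s: s.start_bp)
        for a, b in zip(lst, lst[1:]):
            assert a.end_bp < b.start_bp


def test_detect_roh_monotone_in_thresholds():
    rng = np.random.default_rng(123)
    g, pos = _random_instance(rng)
    ds = make_dataset(g, pos)
    strict = detect_roh(ds, RohParams(window_snps=20, min_snps=20,
                                      min_length_bp=800_000))
    loose = detect_roh(ds, RohParams(window_snps=20, min_snps=10,
                                     min_length_bp=400_000))
    strict_keys = {(s.sample_id, s.start_bp, s.end_bp) for s in strict}
    loose_keys = {(s.sample_id, s.start_bp, s.end_bp) for s in loose}
    assert strict_keys <= loose_keys


def test_detect_roh_fully_heterozygous_is_empty():
    ds = make_dataset(np.ones((3, 100), dtype=np.int8),
                      np.arange(100) * 30_000 + 1)
    assert detect_roh(ds, RohParams(window_snps=20, min_snps=5)) == []


def test_detect_roh_recovers_planted_ibd_tract():
    from rohkit.simulate import SimConfig, simulate_population

    cfg = SimConfig(n_chromosomes=1, chromosome_length_bp=60_000_000,
                    n_snps_per_chromosome=1800, effective_size=30,
                    n_generations=0, sample_size=40,
                    mating_design="full_sib_offspring", seed=21)
    ds, truth = simulate_population(cfg)
    params = RohParams()
    segs = detect_roh(ds, params)
    by_sample = {}
    for s in segs:
        by_sample.setdefault(s.sample_id, []).append(s)
    checked = 0
    for sid, tracts in truth.ibd_tracts.items():
        for t in tracts:
            if t.length_bp < 10_000_000:
                continue
            checked += 1
            cover = sum(max(0, min(s.end_bp, t.end_bp) - max(s.start_bp, t.start_bp))
                        for s in by_sample.get(sid, []))
            assert cover >= 0.95 * t.length_bp, (sid, t)
    assert checked > 0


# --- summaries --------------------------------------------------------------

def _seg(sample, length_mb, chrom=1, pop="p1", start=1_000_000):
    return RohSegment(sample_id=sample, population=pop, chromosome=chrom,
                      start_bp=start, end_bp=start + int(length_mb * 1e6),
                      n_snps=100)


def test_summarize_lengths_binning_and_fractions():
    segs = [_seg("a", 1), _seg("a", 6), _seg("b", 25)]
    df = summarize_lengths(segs)
    by_class = df.set_index("length_class")
    assert by_class.loc["0.5-5", "count"] == 1
    assert by_class.loc["5-10", "count"] == 1
    assert by_class.loc[">20", "count"] == 1
    assert df["fraction"].sum() == pytest.approx(1.0)
    assert by_class.loc[">20", "mean_sum_per_animal_mb"] == pytest.approx(25 / 2)


def test_summarize_lengths_empty():
    df = summarize_lengths([])
    assert df.empty


def test_per_chromosome_counts_correlations():
    lengths = {1: 100e6, 2: 200e6, 3: 300e6}
    segs = ([_seg("a", 1, chrom=1)] + [_seg("a", 1, chrom=2)] * 2
            + [_seg("a", 1, chrom=3)] * 3)
    table, corr, avg = per_chromosome_counts(segs, lengths)
    assert corr["p1"] == pytest.approx(1.0)
    assert avg == pytest.approx(1.0)
    # constant counts -> degenerate, signalled as nan
    segs_const = [_seg("a", 1, chrom=c) for c in (1, 2, 3)]
    _, corr2, avg2 = per_chromosome_counts(segs_const, lengths)
    assert math.isnan(corr2["p1"]) and math.isnan(avg2)
    with pytest.raises(ValueError):
        per_chromosome_counts(segs, {1: 100e6, 2: 200e6})
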