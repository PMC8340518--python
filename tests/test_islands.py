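"""ROH incidence tracks, island calling, sharing and gene annotation."""

import numpy as np
import pytest

from rohkit.islands import (GeneInterval, IncidenceTrack, RohIsland,
                            annotate_islands, call_islands, classify_shared,
                            island_threshold, read_gene_intervals, snp_incidence)
from rohkit.roh import RohSegment
from conftest import make_dataset


def _seg(sample, chrom, start, end, pop="pop1"):
    return RohSegment(sample_id=sample, population=pop, chromosome=chrom,
                      start_bp=start, end_bp=end, n_snps=10)


def _dataset(n_samples=10, n_markers=50, pops=None):
    g = np.zeros((n_samples, n_markers), dtype=np.int8)
    return make_dataset(g, np.arange(n_markers) * 100_000 + 1,
                        populations=pops or ["pop1"] * n_samples)


def _track(props, population="pop1", n=10):
    props = np.asarray(props, dtype=float)
    return IncidenceTrack(population=population, n_individuals=n,
                          counts=(props * n).astype(int), proportions=props)


# --- incidence --------------------------------------------------------------

def test_incidence_single_segment_counts_covered_markers():
    ds = _dataset(n_samples=10)
    segs = [_seg("s0", 1, 1, 900_001)]  # covers markers at 1..900,001
    track = snp_incidence(segs, ds, "pop1")
    assert track.counts[:10].tolist() == [1] * 10
    assert track.counts[10:].sum() == 0
    assert np.all(track.proportions[:10] == pytest.approx(0.1))


def test_incidence_caps_at_one_per_individual_and_respects_population():
    ds = _dataset(n_samples=4, pops=["A", "A", "B", "B"])
    segs = [_seg("s0", 1, 1, 500_001, pop="A"), _seg("s2", 1, 1, 500_001, pop="B")]
    track_a = snp_incidence(segs, ds, "A")
    assert track_a.counts.max() == 1
    assert track_a.n_individuals == 2
    assert track_a.proportions.max() == pytest.approx(0.5)


def test_incidence_shared_sweep_fraction():
    from rohkit.roh import RohParams, detect_roh
    from rohkit.simulate import SimConfig, plant_sweep, simulate_population

    # outbred founder children: essentially no background ROH, so the
    # incidence inside the swept region reflects the carrier fraction alone
    ds, _ = simulate_population(SimConfig(
        n_chromosomes=2, chromosome_length_bp=50_000_000,
        n_snps_per_chromosome=1300, effective_size=50, n_generations=0,
        sample_size=40, seed=13))
    region = (2, 10_000_000, 18_000_000)
    swept = plant_sweep(ds, region, carrier_fraction=0.4, seed=5)
    segs = detect_roh(swept, RohParams(min_snps=20))
    track = snp_incidence(segs, swept, "POP1")
    in_region = ((swept.chromosomes == 2)
                 & (swept.positions >= region[1] + 1_000_000)
                 & (swept.positions <= region[2] - 1_000_000))
    assert track.proportions[in_region].mean() == pytest.approx(0.4, abs=0.08)


# --- threshold --------------------------------------------------------------

def test_threshold_rank_rule_single_extreme():
    props = np.full(1000, 0.1)
    props[123] = 0.9
    track = _track(props)
    thr = island_threshold(track, top_fraction=0.001)
    assert thr == pytest.approx(0.9)
    assert int((track.proportions >= thr).sum()) == 1


def test_threshold_all_tied_includes_everything():
    track = _track(np.full(200, 0.25))
    thr = island_threshold(track, top_fraction=0.001)
    assert thr == pytest.approx(0.25)
    assert int((track.proportions >= thr).sum()) == 200


def test_threshold_candidate_count_at_least_rank():
    rng = np.random.default_rng(0)
    props = rng.integers(0, 11, size=5000) / 10.0
    track = _track(props)
    for frac in (0.001, 0.01, 0.1):
        thr = island_threshold(track, top_fraction=frac)
        rank = int(np.ceil(frac * props.size))
        assert int((props >= thr).sum()) >= rank
    with pytest.raises(ValueError):
        island_threshold(_track(np.array([])), 0.001)


# --- island calling ---------------------------------------------------------

def test_call_islands_adjacency_and_partition():
    ds = _dataset(n_samples=10, n_markers=30)
    props = np.zeros(30)
    props[5:10] = 0.8
    props[20] = 0.9
    track = _track(props)
    islands = call_islands(track, 0.8, ds)
    assert len(islands) == 2
    five, one = sorted(islands, key=lambda i: -i.n_snps)
    assert five.n_snps == 5 and one.n_snps == 1
    members = sorted(j for isl in islands for j in isl.member_indices)
    assert members == [5, 6, 7, 8, 9, 20]  # candidates partitioned exactly


def test_call_islands_empty_and_threshold_monotonicity():
    ds = _dataset(n_samples=10, n_markers=30)
    props = np.zeros(30)
    props[5:15] = np.linspace(0.5, 0.9, 10)
    track = _track(props)
    assert call_islands(track, 0.95, ds) == []
    low = {i.member_indices for i in call_islands(track, 0.5, ds)}
    high = {i.member_indices for i in call_islands(track, 0.7, ds)}
    low_members = set().union(*low) if low else set()
    high_members = set().union(*high) if high else set()
    assert high_members <= low_members


def test_call_islands_does_not_join_across_chromosomes():
    g = np.zeros((5, 20), dtype=np.int8)
    ds = make_dataset(g, list(np.arange(10) * 100_000 + 1) * 2,
                      chromosomes=[1] * 10 + [2] * 10)
    props = np.zeros(20)
    props[8:12] = 1.0  # crosses the chromosome boundary
    islands = call_islands(_track(props, n=5), 0.5, ds)
    assert len(islands) == 2
    assert sorted(i.chromosome for i in islands) == [1, 2]


# --- shared / specific classification --------------------------------------

def _island(pop, chrom, start, end):
    return RohIsland(population=pop, chromosome=chrom, start_bp=start,
                     end_bp=end, n_snps=5, threshold=0.3, member_indices=())


def test_classify_identical_interval_all_shared():
    by_pop = {p: [_island(p, 1, 100, 200)] for p in ("A", "B", "C")}
    df = classify_shared(by_pop)
    assert len(df) == 1
    assert bool(df.iloc[0]["common_to_all"])


def test_classify_disjoint_all_specific():
    by_pop = {"A": [_island("A", 1, 100, 200)],
              "B": [_island("B", 1, 300, 400)],
              "C": [_island("C", 2, 100, 200)]}
    df = classify_shared(by_pop)
    assert len(df) == 3
    assert df["population_specific"].all()


def test_classify_chained_overlap_merges_cluster():
    # A:[100,200], B:[150,300], C:[250,400] chain into one cluster of all three
    by_pop = {"A": [_island("A", 1, 100, 200)],
              "B": [_island("B", 1, 150, 300)],
              "C": [_island("C", 1, 250, 400), _island("C", 2, 10, 20)]}
    df = classify_shared(by_pop)
    chained = df[df["chromosome"] == 1]
    assert len(chained) == 1
    assert chained.iloc[0]["populations"] == "A,B,C"
    assert bool(chained.iloc[0]["common_to_all"])
    # order invariance
    df2 = classify_shared(dict(reversed(list(by_pop.items()))))
    assert len(df2) == len(df)
    assert set(df2["populations"]) == set(df["populations"])


# --- gene annotation --------------------------------------------------------

def test_annotate_overlap_rules():
    isl = _island("A", 1, 1000, 2000)
    inside = GeneInterval("IN", 1, 1200, 1400)
    touching = GeneInterval("EDGE", 1, 2000, 2500)
    before = GeneInterval("OUT", 1, 1, 999)  # ends 1 bp before island start
    other_chrom = GeneInterval("CHR2", 2, 1000, 2000)
    mapping, union = annotate_islands([isl], [inside, touching, before, other_chrom])
    names = [g.name for g in mapping[isl]]
    assert names == ["IN", "EDGE"]
    assert union == ["IN", "EDGE"]


def test_annotate_matches_hand_intersection_and_dedup():
    islands = [_island("A", 1, 1000, 2000), _island("A", 2, 5000, 6000)]
    genes = [GeneInterval("G1", 1, 900, 1100), GeneInterval("G2", 1, 2500, 2600),
             GeneInterval("G3", 2, 5500, 5600), GeneInterval("G4", 2, 6000, 7000),
             GeneInterval("G1", 2, 5900, 5950)]
    mapping, union = annotate_islands(islands, genes)
    assert [g.name for g in mapping[islands[0]]] == ["G1"]
    assert [g.name for g in mapping[islands[1]]] == ["G3", "G4", "G1"]
    assert union == ["G1", "G3", "G4"]  # deduplicated across islands


def test_read_gene_intervals_gff_and_bed(tmp_path):
    gff = tmp_path / "genes.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1;Name=ALPHA\n"
        "1\tsrc\tmRNA\t100\t200\t.\t+\t.\tID=t1;Parent=g1\n"
        "chr2\tsrc\tgene\t300\t400\t.\t-\t.\tID=g2\n")
    genes = read_gene_intervals(gff)
    assert [(g.name, g.chromosome, g.start_bp, g.end_bp) for g in genes] == [
        ("ALPHA", 1, 100, 200), ("g2", 2, 300, 400)]
    bed = tmp_path / "genes.bed"
    bed.write_text("1\t99\t200\tBETA\t0\t+\n")
    (b,) = read_gene_intervals(bed)
    assert (b.name, b.start_bp, b.end_bp, b.strand) == ("BETA", 100, 200, "+")


def test_planted_sweep_recovered_as_top_island(dense_wf_dataset):
    from rohkit.roh import RohParams, detect_roh
    from rohkit.simulate import plant_sweep

    ds, _ = dense_wf_dataset
    region = (1, 20_000_000, 30_000_000)
    swept = plant_sweep(ds, region, carrier_fraction=0.5, seed=9)
    segs = detect_roh(swept, RohParams(min_snps=20))
    track = snp_incidence(segs, swept, "POP1")
    thr = island_threshold(track, 0.001)
    islands = call_islands(track, thr, swept)
    assert islands
    top = max(islands, key=lambda i: i.n_snps)
    assert top.chromosome == 1
    assert top.start_bp >= region[1] - 1_000_000
    assert top.end_bp <= region[2] + 1_000_000
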