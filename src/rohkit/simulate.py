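"""Forward Wright-Fisher genotype simulation with exact IBD-tract truth.

Each haplotype is a mosaic of founder-haplotype segments, stored as
(breakpoints, founder labels).  Offspring gametes recombine as a Poisson
crossover process along the chromosome (rate set by the cM/Mb map), so the
ancestry of every base pair is tracked exactly.  A sampled individual's true
identity-by-descent (IBD) tracts are the intervals where its two haplotypes
carry the same founder-haplotype label - i.e. genomic segments inherited from
one founder haplotype through both parents.

Genotypes are read off the ancestry mosaics at array-like SNP positions whose
founder alleles are drawn from a uniform(0.05, 0.95) frequency spectrum, then
optionally masked with missing calls.  Mating designs:

``random``
    burn-in at constant size Ne, then each sampled individual is the child of
    two distinct random parents (outbred apart from background drift IBD).
``full_sib_offspring``
    each sampled individual is the child of a full-sib pair (expected
    pedigree F = 1/4 relative to the sibs' parents' generation).
``half_sib_offspring``
    child of a half-sib pair (expected pedigree F = 1/8).

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genotypes import MISSING, GenotypeDataset, Marker, write_plink

__all__ = ["SimConfig", "TruthSet", "IbdTract", "simulate_population",
           "plant_sweep", "write_fixture"]

_DESIGNS = ("random", "full_sib_offspring", "half_sib_offspring")
_EXPECTED_F = {"random": 0.0, "full_sib_offspring": 0.25, "half_sib_offspring": 0.125}


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    Defaults emulate an array-genotyped livestock population: 26 autosomes,
    SNPs every ~50 kb, a cM/Mb ratio of 1.415 and a small missing-call rate.
    """

    n_chromosomes: int = 26
    chromosome_length_bp: int = 100_000_000
    n_snps_per_chromosome: int = 2_000
    cm_per_mb: float = 1.415
    effective_size: int = 100
    n_generations: int = 50
    sample_size: int = 100
    missing_rate: float = 0.0
    mating_design: str = "random"
    population_label: str = "POP1"
    seed: int = 0
    track_drift: bool = False

    def __post_init__(self) -> None:
        if min(self.n_chromosomes, self.chromosome_length_bp,
               self.n_snps_per_chromosome, self.effective_size,
               self.sample_size) < 1 or self.n_generations < 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.mating_design not in _DESIGNS:
            raise ValueError(f"mating_design must be one of {_DESIGNS}")

    @property
    def morgans_per_chromosome(self) -> float:
        return (self.chromosome_length_bp / 1e6) * self.cm_per_mb / 100.0


@dataclass(frozen=True)
class IbdTract:
    chromosome: int
    start_bp: int
    end_bp: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class TruthSet:
    """Ground truth for a simulated dataset."""

    ibd_tracts: dict[str, list[IbdTract]]
    realized_ibd_fraction: dict[str, float]
    expected_pedigree_f: float
    drift_frequencies: np.ndarray | None = None  # (gens+1, n_snps chrom 1)


# one haplotype on one chromosome: (segment start positions, founder labels)
Hap = tuple[np.ndarray, np.ndarray]


def _recombine(hap_a: Hap, hap_b: Hap, length_bp: int, morgans: float,
               rng: np.random.Generator) -> Hap:
    """One gamete from a parent's two chromosome haplotypes."""
    n_cross = rng.poisson(morgans)
    cur = int(rng.integers(2))
    if n_cross == 0:
        return (hap_a, hap_b)[cur]
    cuts = np.sort(rng.integers(2, length_bp + 1, size=n_cross)).astype(np.int64)
    cuts = np.unique(cuts)
    haps = (hap_a, hap_b)
    bounds = np.concatenate([[1], cuts, [length_bp + 1]])
    out_breaks: list[np.ndarray] = []
    out_labels: list[np.ndarray] = []
    for k in range(len(bounds) - 1):
        lo, hi = int(bounds[k]), int(bounds[k + 1])
        breaks, labels = haps[cur]
        i0 = int(np.searchsorted(breaks, lo, side="right")) - 1
        i1 = int(np.searchsorted(breaks, hi, side="left"))
        seg_breaks = breaks[i0:i1].copy()
        seg_breaks[0] = lo
        out_breaks.append(seg_breaks)
        out_labels.append(labels[i0:i1])
        cur ^= 1
    breaks = np.concatenate(out_breaks)
    labels = np.concatenate(out_labels)
    keep = np.concatenate([[True], labels[1:] != labels[:-1]])
    return breaks[keep], labels[keep]


def _gamete(parent, config: SimConfig, rng: np.random.Generator):
    return [_recombine(parent[c][0], parent[c][1], config.chromosome_length_bp,
                       config.morgans_per_chromosome, rng)
            for c in range(config.n_chromosomes)]


def _founders(n: int, config: SimConfig) -> list:
    pop = []
    for i in range(n):
        ind = []
        for _c in range(config.n_chromosomes):
            ind.append((
                (np.array([1], dtype=np.int64), np.array([2 * i], dtype=np.int64)),
                (np.array([1], dtype=np.int64), np.array([2 * i + 1], dtype=np.int64)),
            ))
        pop.append(ind)
    return pop


def _child(pop, config, rng, parents=None):
    if parents is None:
        i, j = rng.choice(len(pop), size=2, replace=False)
        parents = (pop[i], pop[j])
    return [(g1, g2) for g1, g2 in zip(_gamete(parents[0], config, rng),
                                       _gamete(parents[1], config, rng))]


def _ibd_tracts(individual, config: SimConfig) -> list[IbdTract]:
    tracts: list[IbdTract] = []
    L = config.chromosome_length_bp
    for c, (hap0, hap1) in enumerate(individual, start=1):
        b0, l0 = hap0
        b1, l1 = hap1
        bounds = np.unique(np.concatenate([b0, b1, [L + 1]]))
        run_start = None
        for k in range(len(bounds) - 1):
            lo = int(bounds[k])
            lab0 = l0[np.searchsorted(b0, lo, side="right") - 1]
            lab1 = l1[np.searchsorted(b1, lo, side="right") - 1]
            if lab0 == lab1:
                if run_start is None:
                    run_start = lo
            elif run_start is not None:
                tracts.append(IbdTract(c, run_start, int(bounds[k]) - 1))
                run_start = None
        if run_start is not None:
            tracts.append(IbdTract(c, run_start, L))
    return tracts


def _hap_alleles(hap: Hap, positions: np.ndarray,
                 founder_alleles: np.ndarray) -> np.ndarray:
    breaks, labels = hap
    seg = np.searchsorted(breaks, positions, side="right") - 1
    return founder_alleles[labels[seg], np.arange(positions.size)]


def simulate_population(config: SimConfig) -> tuple[GenotypeDataset, TruthSet]:
    """Simulate a genotyped sample with exact IBD truth.

    Burn-in runs ``n_generations`` Wright-Fisher generations at constant size
    ``effective_size`` from unrelated founders; the sampled individuals are
    then produced according to ``mating_design``.
    """
    rng = np.random.default_rng(config.seed)
    L = config.chromosome_length_bp
    m = config.n_snps_per_chromosome

    # marker map: array-like, roughly even spacing with jitter, strictly increasing
    positions = []
    for _c in range(config.n_chromosomes):
        grid = np.linspace(1, L, m + 2)[1:-1]
        jitter = rng.uniform(-0.4, 0.4, size=m) * (L / (m + 1))
        pos = np.unique(np.round(grid + jitter).astype(np.int64))
        while pos.size < m:  # rare collision after rounding
            extra = rng.integers(1, L + 1, size=m - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        positions.append(pos[:m])

    n_founder_haps = 2 * config.effective_size
    freqs = [rng.uniform(0.05, 0.95, size=m) for _ in range(config.n_chromosomes)]
    founder_alleles = [
        (rng.random((n_founder_haps, m)) < f).astype(np.int8) for f in freqs
    ]

    pop = _founders(config.effective_size, config)
    drift = None
    if config.track_drift:
        drift = np.empty((config.n_generations + 1, m))
        drift[0] = _population_freq(pop, positions[0], founder_alleles[0], 0)
    for gen in range(config.n_generations):
        pop = [_child(pop, config, rng) for _ in range(config.effective_size)]
        if config.track_drift:
            drift[gen + 1] = _population_freq(pop, positions[0], founder_alleles[0], 0)

    sampled = []
    for _k in range(config.sample_size):
        if config.mating_design == "random":
            sampled.append(_child(pop, config, rng))
        elif config.mating_design == "full_sib_offspring":
            i, j = rng.choice(len(pop), size=2, replace=False)
            sib1 = _child(pop, config, rng, parents=(pop[i], pop[j]))
            sib2 = _child(pop, config, rng, parents=(pop[i], pop[j]))
            sampled.append(_child(pop, config, rng, parents=(sib1, sib2)))
        else:  # half_sib_offspring
            i, j, k = rng.choice(len(pop), size=3, replace=False)
            sib1 = _child(pop, config, rng, parents=(pop[i], pop[j]))
            sib2 = _child(pop, config, rng, parents=(pop[i], pop[k]))
            sampled.append(_child(pop, config, rng, parents=(sib1, sib2)))

    markers = []
    for c in range(config.n_chromosomes):
        for j, p in enumerate(positions[c]):
            markers.append(Marker(id=f"snp{c + 1}_{j + 1}", chromosome=c + 1,
                                  position_bp=int(p)))
    geno = np.empty((config.sample_size, len(markers)), dtype=np.int8)
    for i, ind in enumerate(sampled):
        cols = []
        for c in range(config.n_chromosomes):
            a0 = _hap_alleles(ind[c][0], positions[c], founder_alleles[c])
            a1 = _hap_alleles(ind[c][1], positions[c], founder_alleles[c])
            cols.append((a0 + a1).astype(np.int8))
        geno[i] = np.concatenate(cols)
    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = MISSING

    sample_ids = [f"ind{i + 1}" for i in range(config.sample_size)]
    dataset = GenotypeDataset(markers=markers, sample_ids=sample_ids,
                              populations=[config.population_label] * config.sample_size,
                              genotypes=geno)

    genome_bp = config.n_chromosomes * L
    tract_map: dict[str, list[IbdTract]] = {}
    frac: dict[str, float] = {}
    for sid, ind in zip(sample_ids, sampled):
        tracts = _ibd_tracts(ind, config)
        tract_map[sid] = tracts
        frac[sid] = sum(t.length_bp for t in tracts) / genome_bp
    truth = TruthSet(ibd_tracts=tract_map, realized_ibd_fraction=frac,
                     expected_pedigree_f=_EXPECTED_F[config.mating_design],
                     drift_frequencies=drift)
    return dataset, truth


def _population_freq(pop, positions, founder_alleles, chrom_index):
    alleles = [
        _hap_alleles(ind[chrom_index][h], positions, founder_alleles)
        for ind in pop for h in (0, 1)
    ]
    return np.mean(alleles, axis=0)


def plant_sweep(dataset: GenotypeDataset, region: tuple[int, int, int],
                carrier_fraction: float, seed: int = 0) -> GenotypeDataset:
    """Overwrite a region with a shared homozygous haplotype in a sample subset.

    ``region`` is (chromosome, start_bp, end_bp).  In ``carrier_fraction`` of
    the samples (chosen at random from the seed) every SNP in the region is set
    to twice a shared haplotype allele, creating a block of ROH incidence
    approximately equal to the carrier fraction.
    """
    chrom, start, end = region
    if not 0.0 <= carrier_fraction <= 1.0:
        raise ValueError("carrier_fraction must be in [0, 1]")
    in_region = (dataset.chromosomes == chrom) & (dataset.positions >= start) \
        & (dataset.positions <= end)
    if not in_region.any():
        raise ValueError("region contains no markers / lies outside the map")
    rng = np.random.default_rng(seed)
    n_carriers = int(round(carrier_fraction * dataset.n_samples))
    carriers = rng.choice(dataset.n_samples, size=n_carriers, replace=False)
    hap = (rng.random(int(in_region.sum())) < 0.5).astype(np.int8)
    geno = dataset.genotypes.copy()
    for i in carriers:
        geno[i, in_region] = 2 * hap
    return GenotypeDataset(markers=dataset.markers, sample_ids=dataset.sample_ids,
                           populations=dataset.populations, genotypes=geno)


def write_fixture(dataset: GenotypeDataset, truth: TruthSet,
                  directory: str | Path, config: SimConfig | None = None,
                  prefix: str = "sim") -> None:
    """Write a PLINK trio, the IBD truth table and the config snapshot."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_plink(dataset, directory / prefix)
    with (directory / "truth_ibd.tsv").open("w") as fh:
        fh.write("sample\tchromosome\tstart_bp\tend_bp\n")
        for sid, tracts in truth.ibd_tracts.items():
            for t in tracts:
                fh.write(f"{sid}\t{t.chromosome}\t{t.start_bp}\t{t.end_bp}\n")
    snapshot = {
        "expected_pedigree_f": truth.expected_pedigree_f,
        "config": asdict(config) if config is not None else None,
    }
    (directory / "truth_config.json").write_text(json.dumps(snapshot, indent=2) + "\n")
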