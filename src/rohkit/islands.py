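"""ROH islands: genomic regions most commonly locked in homozygous runs.

Per population, each SNP is scored by the fraction of individuals whose ROH
cover its position (the incidence track).  The island threshold is the
incidence of the SNP at rank ``ceil(top_fraction * n_markers)`` of the
descending incidence distribution (default top 0.1%); all SNPs at or above
that value are candidates (ties included).  Maximal stretches of
map-consecutive candidates on one chromosome form islands, which can then be
classified as shared or population-specific by physical overlap and annotated
with overlapping genes from a GFF3 or BED interval file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeDataset
from .roh import RohSegment

__all__ = [
    "IncidenceTrack",
    "RohIsland",
    "GeneInterval",
    "snp_incidence",
    "island_threshold",
    "call_islands",
    "classify_shared",
    "annotate_islands",
    "read_gene_intervals",
]


@dataclass
class IncidenceTrack:
    """Per-marker ROH incidence for one population."""

    population: str
    n_individuals: int
    counts: np.ndarray      # individuals with a ROH covering each marker
    proportions: np.ndarray


@dataclass(frozen=True)
class RohIsland:
    """A maximal run of map-consecutive above-threshold SNPs (1-based, inclusive)."""

    population: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    threshold: float
    member_indices: tuple[int, ...]  # marker-column indices of member SNPs


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic footprint (1-based, inclusive)."""

    name: str
    chromosome: int
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("gene interval start must not exceed end")


def snp_incidence(segments: list[RohSegment], dataset: GenotypeDataset,
                  population: str) -> IncidenceTrack:
    """Count, per marker, the population's individuals with a ROH covering it.

    A marker counts for an individual when its position lies within the
    closed interval [start_bp, end_bp] of one of that individual's segments;
    since an individual's segments never overlap, each contributes at most 1.
    """
    pop_samples = [sid for sid, p in zip(dataset.sample_ids, dataset.populations)
                   if p == population]
    n_pop = len(pop_samples)
    counts = np.zeros(dataset.n_markers, dtype=np.int64)
    positions = dataset.positions
    chrom = dataset.chromosomes
    pop_set = set(pop_samples)
    for s in segments:
        if s.sample_id not in pop_set or s.population != population:
            continue
        on_chrom = chrom == s.chromosome
        covered = on_chrom & (positions >= s.start_bp) & (positions <= s.end_bp)
        counts[covered] += 1
    proportions = counts / n_pop if n_pop else counts.astype(float)
    return IncidenceTrack(population=population, n_individuals=n_pop,
                          counts=counts, proportions=proportions)


def island_threshold(track: IncidenceTrack, top_fraction: float = 0.001) -> float:
    """Incidence of the SNP at rank ceil(top_fraction * n) of the descending track.

    All markers with incidence >= the returned value are island candidates
    (ties at the rank-defining value included).
    """
    n = track.proportions.size
    if n == 0:
        raise ValueError("empty incidence track")
    rank = max(1, math.ceil(top_fraction * n))
    ordered = np.sort(track.proportions)[::-1]
    return float(ordered[rank - 1])


def call_islands(track: IncidenceTrack, threshold: float,
                 dataset: GenotypeDataset, strict: bool = False) -> list[RohIsland]:
    """Maximal runs of map-consecutive candidate markers become islands.

    Candidates have incidence >= ``threshold`` (or > with ``strict=True``).
    Single-marker islands are allowed; island bounds are the first and last
    member positions.
    """
    prop = track.proportions
    cand = prop > threshold if strict else prop >= threshold
    positions = dataset.positions
    islands: list[RohIsland] = []
    for c, idx in dataset.chromosome_index().items():
        sel = np.flatnonzero(cand[idx])
        if sel.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(sel) != 1)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sel.size - 1]])
        for s, e in zip(starts, ends):
            members = idx[sel[s:e + 1]]
            islands.append(RohIsland(
                population=track.population, chromosome=int(c),
                start_bp=int(positions[members[0]]),
                end_bp=int(positions[members[-1]]),
                n_snps=int(members.size), threshold=threshold,
                member_indices=tuple(int(j) for j in members)))
    return islands


def classify_shared(islands_by_population: dict[str, list[RohIsland]]) -> pd.DataFrame:
    """Merge physically overlapping islands across populations into clusters.

    Two islands overlap when they share >= 1 bp on the same chromosome.  Each
    cluster row reports its extent, member populations, and whether it is
    common to all populations or specific to exactly one.  The clustering is
    independent of population input order.
    """
    all_pops = sorted(islands_by_population)
    items = sorted(
        ((isl.chromosome, isl.start_bp, isl.end_bp, pop)
         for pop in all_pops for isl in islands_by_population[pop]),
    )
    rows = []
    i = 0
    while i < len(items):
        chrom, start, end, pop = items[i]
        pops = {pop}
        n_members = 1
        j = i + 1
        while j < len(items) and items[j][0] == chrom and items[j][1] <= end:
            end = max(end, items[j][2])
            pops.add(items[j][3])
            n_members += 1
            j += 1
        rows.append({
            "chromosome": chrom, "start_bp": start, "end_bp": end,
            "populations": ",".join(sorted(pops)),
            "n_populations": len(pops), "n_islands": n_members,
            "common_to_all": len(pops) == len(all_pops),
            "population_specific": len(pops) == 1,
        })
        i = j
    return pd.DataFrame(rows)


def annotate_islands(islands: list[RohIsland],
                     genes: list[GeneInterval]
                     ) -> tuple[dict[RohIsland, list[GeneInterval]], list[str]]:
    """Assign genes to islands by >= 1 bp interval overlap.

    Returns the per-island gene lists and the deduplicated, order-preserving
    union of gene names across all islands.
    """
    mapping: dict[RohIsland, list[GeneInterval]] = {}
    union: dict[str, None] = {}
    for isl in islands:
        hits = [g for g in genes
                if g.chromosome == isl.chromosome
                and g.start_bp <= isl.end_bp and g.end_bp >= isl.start_bp]
        mapping[isl] = hits
        for g in hits:
            union.setdefault(g.name, None)
    return mapping, list(union)


def read_gene_intervals(path: str | Path) -> list[GeneInterval]:
    """Read gene intervals from GFF3 (``gene`` features) or 4+-column BED.

    BED coordinates (0-based, half-open) are converted to 1-based inclusive.
    Chromosome labels must be integer autosome labels, optionally prefixed
    with ``chr``.
    """
    path = Path(path)
    genes: list[GeneInterval] = []
    is_gff = path.suffix.lower() in {".gff", ".gff3"}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if is_gff:
            if len(f) < 9 or f[2].lower() != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID") or "?"
            genes.append(GeneInterval(name=name, chromosome=_chrom_label(f[0]),
                                      start_bp=int(f[3]), end_bp=int(f[4]),
                                      strand=f[6]))
        else:
            if len(f) < 4:
                raise ValueError(f"{path}: BED needs >= 4 columns for gene names")
            genes.append(GeneInterval(name=f[3], chromosome=_chrom_label(f[0]),
                                      start_bp=int(f[1]) + 1, end_bp=int(f[2]),
                                      strand=f[5] if len(f) > 5 else "."))
    return genes


def _chrom_label(raw: str) -> int:
    return int(raw[3:] if raw.lower().startswith("chr") else raw)


def islands_to_frame(islands: list[RohIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [(i.population, i.chromosome, i.n_snps, i.start_bp, i.end_bp, i.threshold)
         for i in islands],
        columns=["population", "chromosome", "n_snps", "start_bp", "end_bp",
                 "threshold"])
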