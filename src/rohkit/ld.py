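"""Linkage-disequilibrium decay and Sved-formula effective population size.

r-squared between two SNPs is the squared correlation of haplotype frequencies.
From unphased diploid genotypes every haplotype is directly countable except in
double heterozygotes, whose phase is resolved by expectation-maximisation over
the four haplotype frequencies (initialised at linkage equilibrium).

Historical effective population size N_e(t) at t generations before sampling is
obtained by rearranging Sved's relation between expected r-squared and the
recombination distance c (in Morgans) separating a SNP pair:

    N_e(t) = 1 / (4 c_t) * (1 / E(r^2 | c_t) - 1),    with  t = 1 / (2 c_t).

Physical distance maps to genetic distance through a single genome-wide
cM-per-Mb ratio; E(r^2 | c_t) is taken as the mean r-squared of the 20-kb
distance class that contains the target physical distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotypes import MISSING, GenotypeDataset

__all__ = [
    "LdBin",
    "MapScale",
    "NeEstimate",
    "r2_pair",
    "ld_decay",
    "ne_at_generation",
    "ne_trajectory",
    "map_scale_from_totals",
]

DEFAULT_GENERATIONS = (1000, 500, 200, 100, 50, 20, 10, 5)


class MonomorphicLocusError(ValueError):
    """r-squared is undefined when a locus is monomorphic among complete pairs."""


@dataclass(frozen=True)
class LdBin:
    """One 20-kb distance class: half-open interval (start, end] in bp."""

    start_bp: int
    end_bp: int
    mean_r2: float
    pair_count: int


@dataclass(frozen=True)
class MapScale:
    """Genome-wide conversion between genetic and physical distance (cM per Mb)."""

    cm_per_mb: float = 1.415

    def __post_init__(self) -> None:
        if self.cm_per_mb <= 0:
            raise ValueError("cm_per_mb must be positive")

    def morgans_to_bp(self, c: float) -> float:
        return (100.0 * c / self.cm_per_mb) * 1e6

    def bp_to_morgans(self, bp: float) -> float:
        return (bp / 1e6) * self.cm_per_mb / 100.0


@dataclass(frozen=True)
class NeEstimate:
    """Effective population size at one ancestral generation."""

    t: float
    c_morgans: float
    target_distance_bp: float
    mean_r2: float | None
    ne: float | None

    @property
    def is_missing(self) -> bool:
        return self.ne is None


def map_scale_from_totals(total_physical_mb: float, total_genetic_cm: float) -> MapScale:
    """Build the map scale from genome totals: cM/Mb = total cM / total Mb."""
    if total_physical_mb <= 0 or total_genetic_cm <= 0:
        raise ValueError("map totals must be positive")
    return MapScale(cm_per_mb=total_genetic_cm / total_physical_mb)


# ---------------------------------------------------------------------------
# r-squared by EM over double-heterozygote phase
# ---------------------------------------------------------------------------

def _pair_loglik(f_bb, p1, p2, t):
    """Multinomial log-likelihood of 3x3 genotype tables at haplotype freq f_bb."""
    f_ba = p1 - f_bb
    f_ab = p2 - f_bb
    f_aa = 1.0 - p1 - p2 + f_bb
    probs = np.empty((f_bb.shape[0], 3, 3))
    probs[:, 2, 2] = f_bb ** 2
    probs[:, 2, 1] = 2 * f_bb * f_ba
    probs[:, 2, 0] = f_ba ** 2
    probs[:, 1, 2] = 2 * f_bb * f_ab
    probs[:, 1, 1] = 2 * (f_bb * f_aa + f_ba * f_ab)
    probs[:, 1, 0] = 2 * f_ba * f_aa
    probs[:, 0, 2] = f_ab ** 2
    probs[:, 0, 1] = 2 * f_ab * f_aa
    probs[:, 0, 0] = f_aa ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = np.where(t > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return (t * lp).sum(axis=(1, 2))


def _em_run(f_bb, p1, p2, n_bb, dh, two_n, lo, hi, max_iter, tol):
    """EM iterations on the (B,B) haplotype frequency from one start point."""
    with np.errstate(invalid="ignore", divide="ignore"):
        for _ in range(max_iter):
            f_aa = f_bb - p1 - p2 + 1.0
            num = f_bb * f_aa
            den = num + (p1 - f_bb) * (p2 - f_bb)
            frac = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.5)
            new = np.clip((n_bb + dh * frac) / two_n, lo, hi)
            diff = np.abs(new - f_bb)
            finite = np.isfinite(diff)
            delta = float(diff[finite].max()) if finite.any() else 0.0
            f_bb = new
            if not np.isfinite(delta) or delta < tol:
                break
    return f_bb


def _em_r2_from_tables(tables: np.ndarray, max_iter: int = 1000,
                       tol: float = 1e-9) -> np.ndarray:
    """Vectorised EM r-squared for a stack of 3x3 genotype-count tables.

    ``tables[k, g1, g2]`` counts samples with genotype pair (g1, g2) at pair k.
    The EM fixed point is taken from three starts (linkage equilibrium and both
    feasible extremes of the free haplotype frequency) and the highest
    multinomial likelihood wins, ties broken toward the larger D-squared.
    Returns r-squared per pair; ``nan`` where a locus is monomorphic among the
    pairwise-complete samples.
    """
    t = np.asarray(tables, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    two_n = 2.0 * t.sum(axis=(1, 2))
    # directly countable haplotypes (B = allele counted by the genotype code)
    n_bb = 2 * t[:, 2, 2] + t[:, 2, 1] + t[:, 1, 2]
    dh = t[:, 1, 1]  # double heterozygotes: BB/aa vs Ba/aB phase ambiguity

    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = (2 * t[:, 2, :].sum(axis=1) + t[:, 1, :].sum(axis=1)) / two_n
        p2 = (2 * t[:, :, 2].sum(axis=1) + t[:, :, 1].sum(axis=1)) / two_n
    poly = (p1 > 0) & (p1 < 1) & (p2 > 0) & (p2 < 1)
    lo = np.maximum(0.0, p1 + p2 - 1.0)
    hi = np.minimum(p1, p2)

    starts = [p1 * p2, lo + 1e-6 * (hi - lo), hi - 1e-6 * (hi - lo)]
    best_f = np.full(p1.shape, np.nan)
    best_ll = np.full(p1.shape, -np.inf)
    best_d2 = np.full(p1.shape, -np.inf)
    for start in starts:
        f = _em_run(np.where(poly, start, np.nan), p1, p2, n_bb, dh, two_n,
                    lo, hi, max_iter, tol)
        ll = _pair_loglik(np.where(poly, f, 0.25), p1, p2, t)
        d2 = (f - p1 * p2) ** 2
        better = (ll > best_ll + 1e-9) | (np.isclose(ll, best_ll) & (d2 > best_d2))
        best_f = np.where(better, f, best_f)
        best_d2 = np.where(better, d2, best_d2)
        best_ll = np.where(better, ll, best_ll)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = best_f - p1 * p2
        r2 = d * d / (p1 * (1 - p1) * p2 * (1 - p2))
    return np.where(poly, np.clip(r2, 0.0, 1.0), np.nan)


def r2_pair(geno1, geno2) -> float:
    """EM-based r-squared between two loci from unphased genotype vectors.

    Uses pairwise-complete samples only.  Raises :class:`MonomorphicLocusError`
    if either locus is monomorphic among them or fewer than two remain.
    """
    g1 = np.asarray(geno1, dtype=np.int64)
    g2 = np.asarray(geno2, dtype=np.int64)
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        raise MonomorphicLocusError("fewer than two pairwise-complete samples")
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (g1[ok], g2[ok]), 1)
    r2 = _em_r2_from_tables(table[None])[0]
    if not np.isfinite(r2):
        raise MonomorphicLocusError("monomorphic locus among pairwise-complete samples")
    return float(r2)


def ld_decay(dataset: GenotypeDataset, max_distance_bp: int = 5_000_000,
             class_width_bp: int = 20_000) -> list[LdBin]:
    """Bin mean r-squared of all intra-chromosomal SNP pairs by physical distance.

    Pairs with 0 < distance <= ``max_distance_bp`` each contribute to exactly one
    half-open class ``(k*w, (k+1)*w]``.  Pairs whose r-squared is undefined
    (either locus monomorphic among complete samples) are dropped.
    """
    n_classes = int(math.ceil(max_distance_bp / class_width_bp))
    sums = np.zeros(n_classes)
    counts = np.zeros(n_classes, dtype=np.int64)

    g = dataset.genotypes
    positions = dataset.positions
    for _, idx in dataset.chromosome_index().items():
        pos = positions[idx]
        sub = g[:, idx]
        ind = np.stack([(sub == k).astype(np.float64) for k in (0, 1, 2)])  # 3 x n_s x m
        m = len(idx)
        # tables for all pairs (j, k>j) within the cap, in blocks
        for j0 in range(0, m, 512):
            j1 = min(j0 + 512, m)
            hi = np.searchsorted(pos, pos[j0:j1] + max_distance_bp, side="right")
            kmax = int(hi.max(initial=j1)) if j1 > j0 else j1
            if kmax <= j0 + 1:
                continue
            # 9 cross-products: tab[a, b, j, k] = sum_s ind[a,s,j] * ind[b,s,k]
            left = ind[:, :, j0:j1]
            right = ind[:, :, j0:kmax]
            tab = np.einsum("asj,bsk->jkab", left, right)
            jj, kk = np.meshgrid(np.arange(j0, j1), np.arange(j0, kmax), indexing="ij")
            dist = pos[kk] - pos[jj]
            sel = (kk > jj) & (dist > 0) & (dist <= max_distance_bp)
            if not sel.any():
                continue
            tables = tab[sel]
            r2 = _em_r2_from_tables(tables)
            valid = np.isfinite(r2)
            cls = (dist[sel][valid] - 1) // class_width_bp
            np.add.at(sums, cls, r2[valid])
            np.add.at(counts, cls, 1)

    bins = []
    for k in range(n_classes):
        mean = float(sums[k] / counts[k]) if counts[k] else float("nan")
        bins.append(LdBin(start_bp=k * class_width_bp,
                          end_bp=min((k + 1) * class_width_bp, max_distance_bp),
                          mean_r2=mean, pair_count=int(counts[k])))
    return bins


# ---------------------------------------------------------------------------
# Sved effective population size
# ---------------------------------------------------------------------------

def ne_at_generation(t: float, ld_bins: list[LdBin],
                     map_scale: MapScale = MapScale()) -> NeEstimate:
    """N_e at ``t`` generations ago from the distance class matching c = 1/(2t)."""
    if t <= 0:
        raise ValueError("generation must be positive")
    c = 1.0 / (2.0 * t)
    target_bp = map_scale.morgans_to_bp(c)
    target = None
    for b in ld_bins:
        if b.start_bp < target_bp <= b.end_bp:
            target = b
            break
    if target is None or target.pair_count == 0 or not np.isfinite(target.mean_r2):
        return NeEstimate(t=t, c_morgans=c, target_distance_bp=target_bp,
                          mean_r2=None, ne=None)
    if target.mean_r2 <= 0:
        raise ZeroDivisionError("mean r-squared of the target class is zero")
    ne = (1.0 / (4.0 * c)) * (1.0 / target.mean_r2 - 1.0)
    return NeEstimate(t=t, c_morgans=c, target_distance_bp=target_bp,
                      mean_r2=target.mean_r2, ne=ne)


def ne_trajectory(dataset: GenotypeDataset,
                  generations=DEFAULT_GENERATIONS,
                  map_scale: MapScale = MapScale(),
                  max_distance_bp: int = 5_000_000,
                  class_width_bp: int = 20_000,
                  ld_bins: list[LdBin] | None = None) -> list[NeEstimate]:
    """One N_e estimate per requested ancestral generation.

    Generations whose target distance falls in a class with no pairs are
    reported with ``ne=None`` rather than fabricated.
    """
    if ld_bins is None:
        ld_bins = ld_decay(dataset, max_distance_bp=max_distance_bp,
                           class_width_bp=class_width_bp)
    return [ne_at_generation(t, ld_bins, map_scale) for t in generations]
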