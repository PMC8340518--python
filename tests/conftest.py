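"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every quantity by direct enumeration
(no shared code with the package) so the tests are genuine cross-checks.
"""

from __future__ import annotations

import math
from fractions import Fraction

import hypothesis
import numpy as np
import pytest

hypothesis.settings.register_profile("deterministic", derandomize=True,
                                     deadline=None)
hypothesis.settings.load_profile("deterministic")

from rohkit.genotypes import MISSING, GenotypeDataset, Marker


def make_dataset(genotypes, positions, chromosomes=None, populations=None,
                 sample_ids=None) -> GenotypeDataset:
    """Build a small dataset from a samples x markers array and a position list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_s, n_m = g.shape
    positions = list(positions)
    chromosomes = list(chromosomes) if chromosomes is not None else [1] * n_m
    markers = [Marker(id=f"m{j}", chromosome=chromosomes[j], position_bp=int(positions[j]))
               for j in range(n_m)]
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    populations = populations or ["pop1"] * n_s
    return GenotypeDataset(markers, list(sample_ids), list(populations), g)


# ---------------------------------------------------------------------------
# oracle: conditional exact Hardy-Weinberg test by full enumeration
# ---------------------------------------------------------------------------

def hwe_enumeration_pvalue(n0: int, n1: int, n2: int) -> float:
    """Exact two-sided HWE p-value via enumeration with rational arithmetic."""
    n = n0 + n1 + n2
    na = 2 * n0 + n1  # copies of the allele counted as 0
    probs = {}
    for het in range(0, min(na, 2 * n - na) + 1):
        if (na - het) % 2:
            continue
        a_hom = (na - het) // 2
        b_hom = n - het - a_hom
        if b_hom < 0:
            continue
        w = (Fraction(math.factorial(n),
                      math.factorial(a_hom) * math.factorial(het) * math.factorial(b_hom))
             * Fraction(2) ** het)
        probs[het] = w
    total = sum(probs.values())
    p_obs = probs[n1] / total
    return float(sum(w for w in probs.values() if Fraction(w, total) <= p_obs) / total)


# ---------------------------------------------------------------------------
# oracle: r-squared by 1-D likelihood grid search
# ---------------------------------------------------------------------------

def r2_grid_oracle(table: np.ndarray, grid: int = 4000) -> float:
    """Maximise the multinomial likelihood over the free haplotype frequency.

    Allele frequencies are fixed at their observed values; the (B,B) haplotype
    frequency is scanned on a coarse grid then refined twice.
    """
    t = np.asarray(table, dtype=float)
    two_n = 2 * t.sum()
    p1 = (2 * t[2].sum() + t[1].sum()) / two_n
    p2 = (2 * t[:, 2].sum() + t[:, 1].sum()) / two_n
    if not (0 < p1 < 1 and 0 < p2 < 1):
        return float("nan")
    lo, hi = max(0.0, p1 + p2 - 1.0), min(p1, p2)

    def loglik(f):
        fba, fab, faa = p1 - f, p2 - f, 1 - p1 - p2 + f
        cell = np.array([
            [faa * faa, 2 * fab * faa, fab * fab],
            [2 * fba * faa, 2 * (f * faa + fba * fab), 2 * f * fab],
            [fba * fba, 2 * f * fba, f * f],
        ])
        with np.errstate(divide="ignore"):
            lp = np.where(t > 0, np.log(np.maximum(cell, 1e-300)), 0.0)
        return (t * lp).sum()

    a, b = lo, hi
    best = lo
    for _ in range(3):  # refine the bracket around the grid optimum
        fs = np.linspace(a, b, grid)
        lls = np.array([loglik(f) for f in fs])
        k = int(np.argmax(lls))
        best = fs[k]
        step = (b - a) / (grid - 1)
        a, b = max(lo, best - step), min(hi, best + step)
    d = best - p1 * p2
    return d * d / (p1 * (1 - p1) * p2 * (1 - p2))


# ---------------------------------------------------------------------------
# oracle: ROH detection by naive window enumeration
# ---------------------------------------------------------------------------

def roh_bruteforce(genotypes, positions, *, window=50, max_het=1, max_missing=1,
                   threshold=0.05, max_gap=500_000, min_density=50_000,
                   min_length=500_000, min_snps=1):
    """Direct re-derivation of the sliding-window ROH scan for one sample's
    one-chromosome genotype vector.  Returns (start_bp, end_bp, n_snps) tuples."""
    g = list(genotypes)
    pos = list(positions)
    m = len(g)
    if m == 0:
        return []
    w = min(window, m)
    windows = [(s, s + w) for s in range(m - w + 1)]
    eligible = []
    for s, e in windows:
        het = sum(1 for x in g[s:e] if x == 1)
        mis = sum(1 for x in g[s:e] if x == MISSING)
        eligible.append(het <= max_het and mis <= max_missing)
    props = []
    for j in range(m):
        cover = [k for k, (s, e) in enumerate(windows) if s <= j < e]
        props.append(sum(eligible[k] for k in cover) / len(cover))
    cand = [j for j in range(m) if props[j] > threshold]
    runs, cur = [], []
    for j in cand:
        if cur and (j != cur[-1] + 1 or pos[j] - pos[cur[-1]] > max_gap):
            runs.append(cur)
            cur = []
        cur.append(j)
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        start, end = pos[run[0]], pos[run[-1]]
        length, n = end - start, len(run)
        if length >= min_length and n >= min_snps and n >= length / min_density:
            out.append((start, end, n))
    return out


@pytest.fixture(scope="session")
def small_wf_dataset():
    """A small outbred Wright-Fisher dataset reused across tests."""
    from rohkit.simulate import SimConfig, simulate_population

    cfg = SimConfig(n_chromosomes=3, chromosome_length_bp=50_000_000,
                    n_snps_per_chromosome=600, effective_size=50,
                    n_generations=20, sample_size=40, missing_rate=0.01, seed=11)
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def dense_wf_dataset():
    """Array-density (~38 kb/SNP) dataset, dense enough for the default ROH scan."""
    from rohkit.simulate import SimConfig, simulate_population

    cfg = SimConfig(n_chromosomes=2, chromosome_length_bp=50_000_000,
                    n_snps_per_chromosome=1300, effective_size=50,
                    n_generations=15, sample_size=40, missing_rate=0.01, seed=12)
    return simulate_population(cfg)
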