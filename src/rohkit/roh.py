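"""Sliding-window detection of runs of homozygosity (ROH).

The scan follows the window-based procedure popularised by PLINK and the
detectRUNS R package:

1. slide a window of ``window_snps`` consecutive SNPs along each chromosome of
   each individual; a window is *eligible* when it contains at most
   ``max_het_per_window`` heterozygous and at most ``max_missing_per_window``
   missing calls;
2. score every SNP by the proportion of windows covering it that are eligible
   (windows are truncated at chromosome ends: only windows that exist count);
3. SNPs whose proportion exceeds ``snp_proportion_threshold`` are run
   candidates; maximal stretches of consecutive candidates are split wherever
   the gap between adjacent SNPs exceeds ``max_gap_bp``;
4. a run is reported when it spans at least ``min_length_bp``, contains at
   least ``min_snps`` SNPs and averages at least one SNP per
   ``min_density_bp_per_snp`` bp.

``min_snps`` defaults to the Lencz false-positive bound
``l = ceil( ln(alpha / (n_snp * n_ind)) / ln(1 - mean_het) )`` so that the
expected number of chance runs across the dataset stays below ``alpha``.

Run length is the distance between the first and last SNP positions
(``end_bp - start_bp``), matching the convention of the detection packages the
procedure derives from.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset, mean_heterozygosity

__all__ = [
    "RohParams",
    "RohSegment",
    "min_snps_lencz",
    "window_homozygosity",
    "assemble_runs",
    "detect_roh",
    "summarize_lengths",
    "per_chromosome_counts",
    "LENGTH_CLASS_BOUNDS_MB",
]

#: Length-class boundaries in Mb: 0.5-5, 5-10, 10-15, 15-20, >20.
LENGTH_CLASS_BOUNDS_MB = (0.5, 5.0, 10.0, 15.0, 20.0, math.inf)
LENGTH_CLASS_LABELS = ("0.5-5", "5-10", "10-15", "15-20", ">20")


@dataclass(frozen=True)
class RohParams:
    """Sliding-window scan settings (defaults are the standard array settings)."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_missing_per_window: int = 1
    snp_proportion_threshold: float = 0.05
    max_gap_bp: int = 500_000
    min_density_bp_per_snp: int = 50_000
    min_length_bp: int = 500_000
    min_snps: int | None = None  # None: use the Lencz bound
    fdr_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.window_snps < 1 or self.min_length_bp < 0 or self.max_gap_bp < 1:
            raise ValueError("window and length parameters must be positive")
        if not 0.0 < self.snp_proportion_threshold < 1.0:
            raise ValueError("snp_proportion_threshold must be in (0, 1)")


@dataclass(frozen=True)
class RohSegment:
    """One homozygous run in one individual (1-based inclusive bp coordinates)."""

    sample_id: str
    population: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def min_snps_lencz(alpha: float, n_snp: int, n_ind: int, mean_het: float) -> int:
    """Minimum SNPs per run bounding the expected chance-run count by ``alpha``.

    ``l = ceil( ln(alpha / (n_snp * n_ind)) / ln(1 - mean_het) )``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_snp <= 0 or n_ind <= 0:
        raise ValueError("counts must be positive")
    if not 0.0 < mean_het < 1.0:
        raise ValueError("mean heterozygosity must be in (0, 1)")
    return int(math.ceil(math.log(alpha / (n_snp * n_ind)) / math.log(1.0 - mean_het)))


def window_homozygosity(sample_genotypes, params: RohParams = RohParams()) -> np.ndarray:
    """Per-SNP proportion of covering windows that are homozygous-eligible.

    ``sample_genotypes`` is one chromosome's genotype vector for one sample.
    On chromosomes shorter than one window the whole chromosome forms a single
    truncated window.
    """
    g = np.asarray(sample_genotypes, dtype=np.int64)
    m = g.size
    if m == 0:
        return np.zeros(0)
    w = min(params.window_snps, m)
    het = (g == 1).astype(np.int64)
    mis = (g == MISSING).astype(np.int64)
    # counts per complete window via cumulative sums
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - w + 1
    win_het = ch[w:] - ch[:n_win]
    win_mis = cm[w:] - cm[:n_win]
    eligible = ((win_het <= params.max_het_per_window)
                & (win_mis <= params.max_missing_per_window)).astype(np.int64)
    # SNP j is covered by windows starting in [max(0, j-w+1), min(j, n_win-1)]
    ce = np.concatenate([[0], np.cumsum(eligible)])
    j = np.arange(m)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    covered = (hi - lo + 1).astype(np.float64)
    good = ce[hi + 1] - ce[lo]
    return good / covered


def assemble_runs(proportions, sample_genotypes, positions, params: RohParams,
                  *, sample_id: str = "", population: str = "",
                  chromosome: int = 0, min_snps: int = 1) -> list[RohSegment]:
    """Turn per-SNP eligibility proportions into filtered run segments.

    Candidates (proportion strictly above the threshold) are grouped into
    maximal consecutive stretches, split at inter-SNP gaps above
    ``max_gap_bp``, then filtered by minimum length, SNP count and density.
    """
    prop = np.asarray(proportions, dtype=np.float64)
    pos = np.asarray(positions, dtype=np.int64)
    cand = prop > params.snp_proportion_threshold
    segments: list[RohSegment] = []
    idx = np.flatnonzero(cand)
    if idx.size == 0:
        return segments
    # break where candidates are non-consecutive in the map or the bp gap is too big
    breaks = (np.diff(idx) != 1) | (np.diff(pos[idx]) > params.max_gap_bp)
    starts = np.concatenate([[0], np.flatnonzero(breaks) + 1])
    ends = np.concatenate([np.flatnonzero(breaks), [idx.size - 1]])
    for s, e in zip(starts, ends):
        run = idx[s:e + 1]
        start_bp, end_bp = int(pos[run[0]]), int(pos[run[-1]])
        length = end_bp - start_bp
        n = int(run.size)
        if length < params.min_length_bp:
            continue
        if n < min_snps:
            continue
        if n < length / params.min_density_bp_per_snp:
            continue
        segments.append(RohSegment(sample_id=sample_id, population=population,
                                   chromosome=chromosome, start_bp=start_bp,
                                   end_bp=end_bp, n_snps=n))
    return segments


def effective_min_snps(dataset: GenotypeDataset, params: RohParams) -> int:
    """Resolve ``params.min_snps``: the Lencz bound (at least 1) unless overridden."""
    if params.min_snps is not None:
        return params.min_snps
    het = mean_heterozygosity(dataset)
    if not 0.0 < het < 1.0:
        return 1
    return max(min_snps_lencz(params.fdr_alpha, dataset.n_markers,
                              dataset.n_samples, het), 1)


def detect_roh(dataset: GenotypeDataset,
               params: RohParams = RohParams()) -> list[RohSegment]:
    """Detect ROH for every sample and chromosome of a QC'd dataset.

    Deterministic given inputs; segments are ordered by sample, then
    chromosome, then start position.
    """
    min_snps = effective_min_snps(dataset, params)
    chrom_idx = dataset.chromosome_index()
    positions = dataset.positions
    out: list[RohSegment] = []
    for i, (sid, pop) in enumerate(zip(dataset.sample_ids, dataset.populations)):
        for c, idx in chrom_idx.items():
            g = dataset.genotypes[i, idx]
            prop = window_homozygosity(g, params)
            out.extend(assemble_runs(prop, g, positions[idx], params,
                                     sample_id=sid, population=pop,
                                     chromosome=int(c), min_snps=min_snps))
    return out


def segments_to_frame(segments: list[RohSegment]) -> pd.DataFrame:
    """Tabulate segments (one row each) for export and summaries."""
    return pd.DataFrame(
        [(s.sample_id, s.population, s.chromosome, s.start_bp, s.end_bp,
          s.n_snps, s.length_bp) for s in segments],
        columns=["sample", "population", "chromosome", "start_bp", "end_bp",
                 "n_snps", "length_bp"],
    )


def summarize_lengths(segments: list[RohSegment],
                      class_bounds_mb=LENGTH_CLASS_BOUNDS_MB) -> pd.DataFrame:
    """Per-population ROH counts, fractions and per-animal mean sums by length class.

    Classes are ``[b_k, b_{k+1})`` Mb.  Fractions sum to 1 within each
    population that has at least one segment.
    """
    bounds = np.asarray(class_bounds_mb, dtype=float) * 1e6
    labels = [f"{class_bounds_mb[k]:g}-{class_bounds_mb[k + 1]:g}".replace("-inf", "+")
              if math.isfinite(class_bounds_mb[k + 1])
              else f">{class_bounds_mb[k]:g}"
              for k in range(len(class_bounds_mb) - 1)]
    rows = []
    df = segments_to_frame(segments)
    if df.empty:
        return pd.DataFrame(columns=["population", "length_class", "count",
                                     "fraction", "mean_sum_per_animal_mb"])
    df["length_class"] = pd.cut(df["length_bp"], bins=bounds, labels=labels,
                                right=False)
    for pop, grp in df.groupby("population", sort=True):
        n_animals = grp["sample"].nunique()
        total = len(grp)
        for lab in labels:
            sub = grp[grp["length_class"] == lab]
            rows.append({
                "population": pop,
                "length_class": lab,
                "count": len(sub),
                "fraction": len(sub) / total if total else 0.0,
                "mean_count_per_animal": len(sub) / n_animals if n_animals else 0.0,
                "mean_length_mb": sub["length_bp"].mean() / 1e6 if len(sub) else 0.0,
                "mean_sum_per_animal_mb": sub["length_bp"].sum() / 1e6 / n_animals
                if n_animals else 0.0,
            })
    return pd.DataFrame(rows)


def per_chromosome_counts(segments: list[RohSegment],
                          chromosome_lengths: dict[int, float]
                          ) -> tuple[pd.DataFrame, dict[str, float], float]:
    """ROH counts per chromosome per population, and count-vs-length correlations.

    Returns the count table, per-population Pearson correlations between
    chromosome ROH count and chromosome length, and their average.  With fewer
    than three chromosomes, or a degenerate (constant) count vector, the
    correlation is ``nan``.
    """
    from scipy.stats import pearsonr

    chroms = sorted(chromosome_lengths)
    if len(chroms) < 3:
        raise ValueError("correlation requires at least 3 chromosomes")
    lengths = np.array([chromosome_lengths[c] for c in chroms], dtype=float)
    df = segments_to_frame(segments)
    pops = sorted(df["population"].unique()) if not df.empty else []
    table_rows = []
    correlations: dict[str, float] = {}
    for pop in pops:
        sub = df[df["population"] == pop]
        counts = np.array([(sub["chromosome"] == c).sum() for c in chroms], dtype=float)
        for c, n in zip(chroms, counts):
            table_rows.append({"population": pop, "chromosome": c, "count": int(n),
                               "chromosome_length": chromosome_lengths[c]})
        if np.ptp(counts) == 0 or np.ptp(lengths) == 0:
            correlations[pop] = float("nan")
        else:
            correlations[pop] = float(pearsonr(counts, lengths)[0])
    valid = [v for v in correlations.values() if np.isfinite(v)]
    avg = float(np.mean(valid)) if valid else float("nan")
    return pd.DataFrame(table_rows), correlations, avg
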