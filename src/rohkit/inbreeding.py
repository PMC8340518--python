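"""Genomic inbreeding coefficients: F_ROH and the excess-homozygosity F_HOM.

F_ROH (McQuillan-type) for an individual is the total length of its runs of
homozygosity divided by the SNP-covered autosome length:

    F_ROH = sum(L_ROH) / L_AUTO,

where L_AUTO is the sum over chromosomes of (max SNP position - min SNP
position).  A per-chromosome variant divides each chromosome's ROH length by
that chromosome's span; span-weighted per-chromosome values sum exactly to the
genome-wide value.

F_HOM is the moment estimator behind ``plink --het``: with O observed
homozygous genotypes over the individual's L called loci and the
Hardy-Weinberg expectation E = sum_j [1 - 2 p_j (1 - p_j) T_j / (T_j - 1)]
(p_j the population allele frequency, T_j the called allele count at locus j),

    F_HOM = (O - E) / (L - E).

It may be negative (less homozygous than expected under random mating).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeDataset
from .roh import RohSegment

__all__ = [
    "AutosomeSpan",
    "InbreedingRecord",
    "autosome_span",
    "f_roh",
    "f_hom",
    "f_hom_all",
    "pearson_correlation",
    "inbreeding_table",
    "breed_summary",
]


@dataclass(frozen=True)
class AutosomeSpan:
    """SNP-covered length per chromosome and their total, in bp."""

    per_chromosome: dict[int, int]
    total: int

    @classmethod
    def from_spans(cls, spans: dict[int, int]) -> "AutosomeSpan":
        return cls(per_chromosome=dict(spans), total=int(sum(spans.values())))


@dataclass
class InbreedingRecord:
    """Per-sample inbreeding coefficients."""

    sample_id: str
    population: str
    f_roh: float
    f_roh_by_chromosome: dict[int, float]
    f_hom: float
    sum_roh_bp: int


def autosome_span(dataset: GenotypeDataset) -> AutosomeSpan:
    """Per-chromosome span (max - min SNP position) and total L_AUTO.

    A chromosome with a single SNP contributes span 0 (warned).
    """
    import warnings

    spans: dict[int, int] = {}
    positions = dataset.positions
    for c, idx in dataset.chromosome_index().items():
        pos = positions[idx]
        span = int(pos.max() - pos.min())
        if len(idx) < 2:
            warnings.warn(f"chromosome {c} has fewer than 2 SNPs; span 0", stacklevel=2)
            span = 0
        spans[int(c)] = span
    return AutosomeSpan.from_spans(spans)


def f_roh(segments_for_sample: list[RohSegment],
          span: AutosomeSpan) -> tuple[float, dict[int, float]]:
    """Genome-wide and per-chromosome F_ROH for one sample's segments."""
    if span.total <= 0:
        raise ValueError("autosome span must be positive")
    per_chrom: dict[int, float] = {}
    total = 0
    for c, c_span in span.per_chromosome.items():
        length = sum(s.length_bp for s in segments_for_sample if s.chromosome == c)
        total += length
        per_chrom[c] = length / c_span if c_span > 0 else 0.0
    return total / span.total, per_chrom


def _hwe_expected_hom(genotypes: np.ndarray) -> np.ndarray:
    """Per-locus expected homozygote probability under HWE with the small-sample
    correction T/(T-1) on 2pq, from population genotype counts."""
    called = genotypes != MISSING
    t_alleles = 2.0 * called.sum(axis=0)
    alt = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(t_alleles > 0, alt / t_alleles, np.nan)
        corr = np.where(t_alleles > 1, t_alleles / (t_alleles - 1.0), np.nan)
        e_hom = 1.0 - 2.0 * p * (1.0 - p) * corr
    return e_hom


def f_hom(dataset: GenotypeDataset, sample: int | str,
          within_population: bool = True) -> float:
    """Excess-homozygosity inbreeding coefficient for one sample.

    Allele frequencies come from the sample's own population by default
    (``within_population=False`` pools all samples).
    """
    return f_hom_all(dataset, within_population=within_population)[_sample_index(dataset, sample)]


def _sample_index(dataset: GenotypeDataset, sample: int | str) -> int:
    if isinstance(sample, str):
        return dataset.sample_ids.index(sample)
    return int(sample)


def f_hom_all(dataset: GenotypeDataset, within_population: bool = True) -> np.ndarray:
    """Vector of F_HOM over all samples."""
    g = dataset.genotypes
    n_s = dataset.n_samples
    out = np.full(n_s, np.nan)
    pops = np.asarray(dataset.populations)
    groups = ([np.flatnonzero(pops == p) for p in dict.fromkeys(dataset.populations)]
              if within_population else [np.arange(n_s)])
    for rows in groups:
        sub = g[rows]
        e_hom = _hwe_expected_hom(sub)
        usable = np.isfinite(e_hom)
        for i, row_idx in enumerate(rows):
            row = sub[i]
            ok = (row != MISSING) & usable
            L = int(ok.sum())
            if L == 0:
                raise ValueError(f"sample {dataset.sample_ids[row_idx]} has no usable loci")
            O = int(((row == 0) | (row == 2))[ok].sum())
            E = float(e_hom[ok].sum())
            if L == E:
                raise ZeroDivisionError("degenerate F_HOM denominator (L == E)")
            out[row_idx] = (O - E) / (L - E)
    return out


def pearson_correlation(x, y) -> float:
    """Product-moment correlation; raises on length < 3 or zero variance."""
    from scipy.stats import pearsonr

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(x, y)[0])


def inbreeding_table(dataset: GenotypeDataset, segments: list[RohSegment],
                     within_population: bool = True) -> list[InbreedingRecord]:
    """Per-sample F_ROH (genome and per chromosome) and F_HOM records."""
    span = autosome_span(dataset)
    fh = f_hom_all(dataset, within_population=within_population)
    by_sample: dict[str, list[RohSegment]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    records = []
    for i, (sid, pop) in enumerate(zip(dataset.sample_ids, dataset.populations)):
        segs = by_sample.get(sid, [])
        fr, per_chrom = f_roh(segs, span)
        records.append(InbreedingRecord(
            sample_id=sid, population=pop, f_roh=fr,
            f_roh_by_chromosome=per_chrom, f_hom=float(fh[i]),
            sum_roh_bp=sum(s.length_bp for s in segs)))
    return records


def breed_summary(records: list[InbreedingRecord],
                  segments: list[RohSegment]) -> pd.DataFrame:
    """Per-population descriptive statistics plus a pooled row.

    Columns: mean/SD of per-animal ROH count, mean/SD segment length (Mb),
    mean/SD F_ROH, mean/SD F_HOM, and r(F_ROH, F_HOM).  Sample SD uses the
    n-1 denominator; single-animal groups get SD ``nan``.
    """
    seg_df = pd.DataFrame(
        [(s.sample_id, s.population, s.length_bp) for s in segments],
        columns=["sample", "population", "length_bp"])
    rec_df = pd.DataFrame(
        [(r.sample_id, r.population, r.f_roh, r.f_hom) for r in records],
        columns=["sample", "population", "f_roh", "f_hom"])
    rows = []
    pops = list(dict.fromkeys(rec_df["population"])) + ["ALL"]
    for pop in pops:
        rec = rec_df if pop == "ALL" else rec_df[rec_df["population"] == pop]
        seg = seg_df if pop == "ALL" else seg_df[seg_df["population"] == pop]
        counts = rec["sample"].map(seg.groupby("sample").size()).fillna(0.0)
        lengths_mb = seg["length_bp"] / 1e6
        try:
            corr = pearson_correlation(rec["f_roh"], rec["f_hom"])
        except ValueError:
            corr = float("nan")
        rows.append({
            "population": pop,
            "n_animals": len(rec),
            "roh_count_mean": counts.mean(),
            "roh_count_sd": counts.std(ddof=1),
            "roh_length_mb_mean": lengths_mb.mean() if len(seg) else 0.0,
            "roh_length_mb_sd": lengths_mb.std(ddof=1),
            "f_roh_mean": rec["f_roh"].mean(),
            "f_roh_sd": rec["f_roh"].std(ddof=1),
            "f_hom_mean": rec["f_hom"].mean(),
            "f_hom_sd": rec["f_hom"].std(ddof=1),
            "r_froh_fhom": corr,
        })
    return pd.DataFrame(rows)
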