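"""Genotype containers, PLINK/VCF input-output and SNP-array quality control.

The central container is :class:`GenotypeDataset`: a samples x markers matrix of
diploid genotype codes ``{0, 1, 2, MISSING}`` counting copies of each marker's
``allele_b``, together with an ordered marker map (chromosome, 1-based bp
position) and per-sample population labels.

PLINK binary convention
-----------------------
.bed files are read and written in SNP-major order (magic bytes
``0x6c 0x1b 0x01``).  The 2-bit codes are interpreted with the A1-counting
convention of ``plink --recode A``: on read, ``allele_b`` is set to .bim
column 5 (A1) so that code ``00`` (homozygous A1) maps to genotype 2,
``11`` (homozygous A2) to 0, ``10`` to 1 and ``01`` to missing.  For VCF input
``allele_b`` is the ALT allele, so genotypes count ALT copies.

Coordinates are 1-based and intervals are inclusive, matching .bim files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MISSING",
    "Marker",
    "GenotypeDataset",
    "QcParams",
    "QcReport",
    "read_plink",
    "write_plink",
    "read_vcf",
    "hwe_exact_pvalue",
    "apply_qc",
    "mean_heterozygosity",
]

#: Sentinel genotype code for a missing call.
MISSING: int = -1

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK code -> genotype (copies of A1 = allele_b); 01 is missing.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised when a PLINK fileset is malformed (bad magic, dimension mismatch)."""


@dataclass(frozen=True)
class Marker:
    """One biallelic SNP: identifier, chromosome label, 1-based bp position, alleles."""

    id: str
    chromosome: int
    position_bp: int
    allele_a: str = "A"
    allele_b: str = "B"


@dataclass
class GenotypeDataset:
    """Samples x markers genotype matrix plus marker map and sample labels.

    ``genotypes[i, j]`` counts copies of ``markers[j].allele_b`` carried by
    sample ``i`` and is one of ``{0, 1, 2, MISSING}``.
    """

    markers: list[Marker]
    sample_ids: list[str]
    populations: list[str]
    genotypes: np.ndarray  # int8, shape (n_samples, n_markers)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_s, n_m = self.genotypes.shape if self.genotypes.size else (
            len(self.sample_ids), len(self.markers))
        if self.genotypes.size:
            if n_s != len(self.sample_ids) or n_m != len(self.markers):
                raise ValueError("genotype matrix shape does not match sample/marker counts")
        if len(self.populations) != len(self.sample_ids):
            raise ValueError("population labels must match sample count")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, missing}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.array([m.chromosome for m in self.markers], dtype=np.int64)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)

    def chromosome_index(self) -> dict[int, np.ndarray]:
        """Map chromosome label -> marker column indices, in map order."""
        chrom = self.chromosomes
        return {c: np.flatnonzero(chrom == c) for c in dict.fromkeys(chrom.tolist())}

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeDataset":
        s = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        m = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeDataset(
            markers=[self.markers[j] for j in m],
            sample_ids=[self.sample_ids[i] for i in s],
            populations=[self.populations[i] for i in s],
            genotypes=self.genotypes[np.ix_(s, m)] if self.genotypes.size else
            np.zeros((len(s), len(m)), dtype=np.int8),
        )

    def validate_map(self, autosomes: set[int] | None = None) -> None:
        """Check that positions strictly increase within each chromosome."""
        for c, idx in self.chromosome_index().items():
            pos = self.positions[idx]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on chromosome {c}")
            if autosomes is not None and c not in autosomes:
                raise ValueError(f"chromosome {c} outside declared autosome set")


@dataclass(frozen=True)
class QcParams:
    """Quality-control thresholds.

    All call-rate and MAF comparisons are strict (keep if value > threshold);
    a locus is removed when its exact Hardy-Weinberg p-value is < ``hwe_alpha``.
    """

    min_locus_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 0.001
    min_sample_call_rate: float = 0.90
    autosomes_only: bool = True
    autosomes: frozenset[int] = frozenset(range(1, 27))
    hwe_per_population: bool = False

    def __post_init__(self) -> None:
        for name in ("min_locus_call_rate", "min_maf", "hwe_alpha", "min_sample_call_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    """Counts of markers/samples removed by each filter, in application order."""

    input_markers: int = 0
    input_samples: int = 0
    removed_non_autosomal: int = 0
    removed_locus_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_sample_call_rate: int = 0
    retained_markers: int = 0
    retained_samples: int = 0

    def check_conservation(self) -> None:
        m = (self.removed_non_autosomal + self.removed_locus_call_rate
             + self.removed_maf + self.removed_hwe + self.retained_markers)
        s = self.removed_sample_call_rate + self.retained_samples
        if m != self.input_markers or s != self.input_samples:
            raise AssertionError("QcReport counts are not conserved")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK ``.bed/.bim/.fam`` trio into a :class:`GenotypeDataset`.

    The .fam family ID (column 1) is used as the population label.
    """
    prefix = Path(path_prefix)
    bim_rows = _read_table(prefix.with_suffix(".bim"))
    fam_rows = _read_table(prefix.with_suffix(".fam"))

    markers = [
        Marker(id=r[1], chromosome=int(r[0]), position_bp=int(r[3]),
               allele_a=r[5], allele_b=r[4])  # allele_b = A1 (bim col 5)
        for r in bim_rows
    ]
    sample_ids = [r[1] for r in fam_rows]
    populations = [r[0] for r in fam_rows]

    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {raw[:3]!r}")
    n_s, n_m = len(sample_ids), len(markers)
    stride = (n_s + 3) // 4  # bytes per SNP, SNP-major
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != stride * n_m:
        raise PlinkFormatError(
            f"{prefix}.bed: expected {stride * n_m} data bytes, found {body.size}")
    if n_m == 0 or n_s == 0:
        geno = np.zeros((n_s, n_m), dtype=np.int8)
    else:
        blocks = body.reshape(n_m, stride)
        # unpack 2-bit codes, little-endian within each byte
        codes = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2)
        codes = codes.reshape(n_m, stride * 4)[:, :n_s]
        geno = _BED_DECODE[codes].T.copy()
    return GenotypeDataset(markers, sample_ids, populations, geno)


def write_plink(dataset: GenotypeDataset, path_prefix: str | Path) -> None:
    """Write a dataset as a PLINK ``.bed/.bim/.fam`` trio (round-trip safe)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with prefix.with_suffix(".bim").open("w") as fh:
        for m in dataset.markers:
            fh.write(f"{m.chromosome}\t{m.id}\t0\t{m.position_bp}\t{m.allele_b}\t{m.allele_a}\n")
    with prefix.with_suffix(".fam").open("w") as fh:
        for sid, pop in zip(dataset.sample_ids, dataset.populations):
            fh.write(f"{pop}\t{sid}\t0\t0\t0\t-9\n")
    n_s, n_m = dataset.n_samples, dataset.n_markers
    stride = (n_s + 3) // 4
    out = np.zeros((n_m, stride * 4), dtype=np.uint8)
    if n_s and n_m:
        enc = np.zeros(256, dtype=np.uint8)
        for g, code in _BED_ENCODE.items():
            enc[np.int16(g) & 0xFF] = code
        codes = enc[dataset.genotypes.T.astype(np.int16) & 0xFF]
        out[:, :n_s] = codes
    packed = (out[:, 0::4] | (out[:, 1::4] << 2) | (out[:, 2::4] << 4) | (out[:, 3::4] << 6))
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.astype(np.uint8).tobytes())


def _read_table(path: Path) -> list[list[str]]:
    if not path.exists():
        raise FileNotFoundError(path)
    rows = []
    for line in path.read_text().splitlines():
        if line.strip():
            rows.append(line.split())
    return rows


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, population: str = "pop1") -> tuple[GenotypeDataset, int]:
    """Read biallelic GT records from a VCF 4.x file.

    Genotypes count ALT copies: ``0/0 -> 0``, ``0/1``/``1/0 -> 1``, ``1/1 -> 2``,
    ``./. -> missing``.  Multiallelic records are skipped; the number skipped is
    returned alongside the dataset.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    markers: list[Marker] = []
    rows: list[np.ndarray] = []
    n_skipped = 0
    for rec in vcf:
        if rec.format("GT") is None and rec.gt_types is None:
            raise ValueError(f"{path}: record without GT field at {rec.CHROM}:{rec.POS}")
        if len(rec.ALT) != 1:
            n_skipped += 1
            continue
        g = np.asarray(rec.gt_types, dtype=np.int8)  # gts012: 0,1,2; 3=missing
        g[g == 3] = MISSING
        rows.append(g)
        markers.append(Marker(id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                              chromosome=int(rec.CHROM), position_bp=int(rec.POS),
                              allele_a=rec.REF, allele_b=rec.ALT[0]))
    if n_skipped:
        warnings.warn(f"{n_skipped} multiallelic record(s) skipped", stacklevel=2)
    geno = (np.vstack(rows).T if rows else
            np.zeros((len(sample_ids), 0), dtype=np.int8))
    ds = GenotypeDataset(markers, sample_ids, [population] * len(sample_ids), geno)
    return ds, n_skipped


# ---------------------------------------------------------------------------
# Statistics used by QC
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Two-sided conditional exact Hardy-Weinberg test for one biallelic locus.

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed configuration.
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_aa_hom + n_het + n_bb_hom
    if n == 0:
        raise ValueError("no genotyped individuals")
    n_rare = 2 * min(n_aa_hom, n_bb_hom) + n_het
    # het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    # unnormalised log-probabilities of P(het | allele counts)
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (hets * np.log(2.0)
            - gammaln(hets + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    p_obs = p[np.searchsorted(hets, n_het)]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def allele_frequencies(genotypes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus allele-b frequency and non-missing call count.

    Monomorphic-or-empty loci with zero calls get frequency ``nan``.
    """
    called = genotypes != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, alt / (2.0 * np.maximum(n_called, 1)), np.nan)
    return freq, n_called


def mean_heterozygosity(dataset: GenotypeDataset) -> float:
    """Mean over loci of the per-locus heterozygote fraction among called genotypes."""
    g = dataset.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    if not n_called.any():
        raise ValueError("dataset has no non-missing genotypes")
    het = (g == 1).sum(axis=0)
    ok = n_called > 0
    return float(np.mean(het[ok] / n_called[ok]))


def apply_qc(dataset: GenotypeDataset,
             params: QcParams | None = None) -> tuple[GenotypeDataset, QcReport]:
    """Apply locus and sample filters in a fixed order and tally removals.

    Order: autosome restriction -> locus call rate -> MAF -> HWE -> sample call
    rate, with allele frequencies recomputed from the surviving loci before the
    MAF and HWE steps.  Applying the same parameters twice is a no-op the second
    time on data that already passed.
    """
    params = params or QcParams()
    report = QcReport(input_markers=dataset.n_markers, input_samples=dataset.n_samples)

    keep_m = np.ones(dataset.n_markers, dtype=bool)
    chrom = dataset.chromosomes
    if params.autosomes_only:
        auto = np.isin(chrom, list(params.autosomes))
        report.removed_non_autosomal = int((~auto).sum())
        keep_m &= auto

    g = dataset.genotypes
    called = g != MISSING
    n_s = dataset.n_samples
    call_rate = called.sum(axis=0) / max(n_s, 1)
    fail_cr = ~(call_rate > params.min_locus_call_rate)
    report.removed_locus_call_rate = int((keep_m & fail_cr).sum())
    keep_m &= ~fail_cr

    freq, _ = allele_frequencies(g)
    maf = np.minimum(freq, 1.0 - freq)
    fail_maf = ~(maf > params.min_maf) | np.isnan(maf)
    report.removed_maf = int((keep_m & fail_maf).sum())
    keep_m &= ~fail_maf

    hwe_idx = np.flatnonzero(keep_m)
    fail_hwe = np.zeros(dataset.n_markers, dtype=bool)
    groups: list[np.ndarray]
    if params.hwe_per_population:
        pops = np.asarray(dataset.populations)
        groups = [np.flatnonzero(pops == p) for p in dict.fromkeys(dataset.populations)]
    else:
        groups = [np.arange(n_s)]
    for j in hwe_idx:
        for rows in groups:
            col = g[rows, j]
            n0 = int((col == 0).sum()); n1 = int((col == 1).sum()); n2 = int((col == 2).sum())
            if n0 + n1 + n2 == 0:
                continue
            if hwe_exact_pvalue(n0, n1, n2) < params.hwe_alpha:
                fail_hwe[j] = True
                break
    report.removed_hwe = int(fail_hwe.sum())
    keep_m &= ~fail_hwe
    report.retained_markers = int(keep_m.sum())

    kept_cols = np.flatnonzero(keep_m)
    sample_cr = (called[:, kept_cols].sum(axis=1) / max(len(kept_cols), 1)
                 if len(kept_cols) else np.ones(n_s))
    keep_s = sample_cr > params.min_sample_call_rate
    report.removed_sample_call_rate = int((~keep_s).sum())
    report.retained_samples = int(keep_s.sum())

    report.check_conservation()
    return dataset.subset(np.flatnonzero(keep_s), kept_cols), report
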