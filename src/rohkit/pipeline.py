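"""End-to-end orchestration: QC -> LD/Ne -> ROH -> inbreeding -> islands.

One YAML config drives the full analysis; every stage writes a plain-text
table (TSV/JSON/BED) to the output directory and the run is summarised in a
RunReport.  Defaults throughout equal the standard array-analysis settings
documented in the individual modules.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeDataset, QcParams, apply_qc, read_plink, read_vcf
from .inbreeding import breed_summary, inbreeding_table
from .islands import (call_islands, classify_shared, island_threshold,
                      islands_to_frame, read_gene_intervals, annotate_islands,
                      snp_incidence)
from .ld import MapScale, DEFAULT_GENERATIONS, ld_decay, ne_trajectory
from .roh import (RohParams, detect_roh, effective_min_snps, per_chromosome_counts,
                  segments_to_frame, summarize_lengths)
from .simulate import SimConfig, simulate_population, write_fixture

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the YAML config layout."""

    input_prefix: str | None = None      # PLINK prefix
    input_vcf: str | None = None
    output_dir: str = "rohkit_out"
    seed: int = 0
    qc: QcParams = field(default_factory=QcParams)
    roh: RohParams = field(default_factory=RohParams)
    map_scale_cm_per_mb: float = 1.415
    ld_max_distance_bp: int = 5_000_000
    ld_class_width_bp: int = 20_000
    generations: tuple[int, ...] = DEFAULT_GENERATIONS
    island_top_fraction: float = 0.001
    run_ld: bool = True
    run_islands: bool = True
    gene_annotation: str | None = None   # GFF3/BED path
    simulate: SimConfig | None = None    # used when no input files are given


@dataclass
class RunReport:
    """Stage-by-stage accounting of one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    stage_rows: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    skipped: list = field(default_factory=list)
    min_snps_per_roh: int | None = None
    island_thresholds: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file into a :class:`PipelineConfig`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = dict(raw)
    if "qc" in kwargs:
        kwargs["qc"] = QcParams(**{k: (frozenset(v) if k == "autosomes" else v)
                                   for k, v in kwargs["qc"].items()})
    if "roh" in kwargs:
        kwargs["roh"] = RohParams(**kwargs["roh"])
    if "simulate" in kwargs and kwargs["simulate"] is not None:
        kwargs["simulate"] = SimConfig(**kwargs["simulate"])
    if "generations" in kwargs:
        kwargs["generations"] = tuple(kwargs["generations"])
    return PipelineConfig(**kwargs)


def _load_dataset(config: PipelineConfig) -> GenotypeDataset:
    if config.input_prefix:
        return read_plink(config.input_prefix)
    if config.input_vcf:
        return read_vcf(config.input_vcf)[0]
    if config.simulate is not None:
        return simulate_population(config.simulate)[0]
    raise ValueError("config must name input_prefix, input_vcf or a simulate block")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run all stages in order, writing tables to ``config.output_dir``.

    Deterministic given the config (and its seed, for simulated input): rerun
    with the same config reproduces byte-identical tables.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config={k: v for k, v in asdict(config).items()})
    stage = "load"
    try:
        t0 = time.perf_counter()
        dataset = _load_dataset(config)
        report.stage_seconds["load"] = round(time.perf_counter() - t0, 3)

        stage = "qc"
        t0 = time.perf_counter()
        dataset, qc_report = apply_qc(dataset, config.qc)
        qc_report.to_json(out / "qc_report.json")
        report.qc = qc_report.__dict__
        report.stage_rows["qc_markers"] = qc_report.retained_markers
        report.stage_rows["qc_samples"] = qc_report.retained_samples
        report.stage_seconds["qc"] = round(time.perf_counter() - t0, 3)

        pops = list(dict.fromkeys(dataset.populations))
        map_scale = MapScale(config.map_scale_cm_per_mb)

        if config.run_ld:
            stage = "ld"
            t0 = time.perf_counter()
            bins = ld_decay(dataset, config.ld_max_distance_bp, config.ld_class_width_bp)
            pd.DataFrame(
                [(b.start_bp / 1e3, b.end_bp / 1e3, b.mean_r2, b.pair_count)
                 for b in bins],
                columns=["class_start_kb", "class_end_kb", "mean_r2", "n_pairs"],
            ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
            estimates = ne_trajectory(dataset, config.generations, map_scale,
                                      ld_bins=bins)
            pd.DataFrame(
                [(e.t, e.c_morgans, e.target_distance_bp, e.mean_r2, e.ne)
                 for e in estimates],
                columns=["t", "c_morgans", "target_bp", "mean_r2", "ne"],
            ).to_csv(out / "ne_trajectory.tsv", sep="\t", index=False)
            report.stage_rows["ld_bins"] = len(bins)
            report.stage_rows["ne_estimates"] = sum(1 for e in estimates if not e.is_missing)
            report.stage_seconds["ld"] = round(time.perf_counter() - t0, 3)
        else:
            report.skipped.append("ld")

        stage = "roh"
        t0 = time.perf_counter()
        report.min_snps_per_roh = effective_min_snps(dataset, config.roh)
        segments = detect_roh(dataset, config.roh)
        segments_to_frame(segments).to_csv(out / "roh_segments.tsv", sep="\t", index=False)
        summarize_lengths(segments).to_csv(out / "roh_length_summary.tsv",
                                           sep="\t", index=False)
        report.stage_rows["roh_segments"] = len(segments)
        report.stage_seconds["roh"] = round(time.perf_counter() - t0, 3)

        stage = "inbreeding"
        t0 = time.perf_counter()
        records = inbreeding_table(dataset, segments)
        chroms = sorted(dataset.chromosome_index())
        rows = []
        for r in records:
            row = {"sample": r.sample_id, "population": r.population,
                   "f_roh": r.f_roh, "f_hom": r.f_hom, "sum_roh_bp": r.sum_roh_bp}
            row.update({f"f_roh_chr{c}": r.f_roh_by_chromosome.get(c, 0.0)
                        for c in chroms})
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "inbreeding.tsv", sep="\t", index=False)
        breed_summary(records, segments).to_csv(out / "breed_summary.tsv",
                                                sep="\t", index=False)
        report.stage_rows["inbreeding_records"] = len(records)
        report.stage_seconds["inbreeding"] = round(time.perf_counter() - t0, 3)

        if config.run_islands:
            stage = "islands"
            t0 = time.perf_counter()
            islands_by_pop = {}
            for pop in pops:
                track = snp_incidence(segments, dataset, pop)
                pd.DataFrame({
                    "chrom": dataset.chromosomes, "pos": dataset.positions,
                    "snp_id": [m.id for m in dataset.markers],
                    "count": track.counts, "proportion": track.proportions,
                }).to_csv(out / f"incidence_{pop}.tsv", sep="\t", index=False)
                thr = island_threshold(track, config.island_top_fraction)
                report.island_thresholds[pop] = thr
                islands_by_pop[pop] = call_islands(track, thr, dataset)
            all_islands = [i for lst in islands_by_pop.values() for i in lst]
            islands_to_frame(all_islands).to_csv(out / "islands.tsv", sep="\t",
                                                 index=False)
            with (out / "islands.bed").open("w") as fh:
                for isl in all_islands:
                    fh.write(f"{isl.chromosome}\t{isl.start_bp - 1}\t{isl.end_bp}"
                             f"\t{isl.population}\n")
            if len(islands_by_pop) >= 2:
                classify_shared(islands_by_pop).to_csv(out / "islands_shared.tsv",
                                                       sep="\t", index=False)
            if config.gene_annotation:
                genes = read_gene_intervals(config.gene_annotation)
                mapping, union = annotate_islands(all_islands, genes)
                rows = [{"population": isl.population, "chromosome": isl.chromosome,
                         "start_bp": isl.start_bp, "end_bp": isl.end_bp,
                         "n_genes": len(gs), "genes": ",".join(g.name for g in gs)}
                        for isl, gs in mapping.items()]
                pd.DataFrame(rows).to_csv(out / "islands_genes.tsv", sep="\t",
                                          index=False)
            report.stage_rows["islands"] = len(all_islands)
            report.stage_seconds["islands"] = round(time.perf_counter() - t0, 3)
        else:
            report.skipped.append("islands")
    except Exception:
        report.failed_stage = stage
        report.write(out / "run_report.json")
        raise
    report.write(out / "run_report.json")
    return report
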