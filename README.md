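# rohkit

Runs of homozygosity (ROH), genomic inbreeding and LD-based effective
population size from diploid SNP-array genotypes.

When both copies of a chromosome segment descend from a single ancestral
haplotype, the segment shows up as an uninterrupted run of homozygous
genotypes. The length, number and genomic placement of such runs carry three
kinds of information that this package extracts:

- **Individual inbreeding.** `F_ROH = ΣL_ROH / L_AUTO` — the fraction of the
  SNP-covered autosome lying in ROH — estimates realized inbreeding without a
  pedigree (McQuillan-type). It is computed genome-wide and per chromosome,
  alongside the excess-homozygosity moment estimator
  `F_HOM = (O − E)/(L − E)` (the statistic behind `plink --het`).
- **Population history.** Pairwise linkage disequilibrium `r²`, binned in
  20-kb physical-distance classes, yields the historical effective population
  size via Sved's relation, `N_e(t) = (1/4c_t)(1/E(r²|c_t) − 1)` with
  `t ≈ 1/(2c_t)`, where physical distance maps to the recombination distance
  `c` through a genome-wide cM/Mb ratio.
- **Selection signatures.** Genomic regions where ROH pile up across
  individuals of a population ("ROH islands", called at the top-0.1% of the
  per-SNP ROH incidence distribution) flag candidate sweeps, and can be
  intersected with gene annotation (GFF3/BED).

ROH are detected with the standard sliding-window scan (50-SNP windows, at
most one heterozygous and one missing call per window, 5% window-eligibility
threshold per SNP, 500-kb maximum gap, 500-kb minimum length, 1 SNP / 50 kb
minimum density, and the Lencz minimum-SNP bound
`l = ⌈ln(α/(n_SNP·n_ind)) / ln(1 − h̄)⌉` against chance runs).

The package is aimed at livestock and conservation geneticists working with
array genotypes (PLINK bed/bim/fam or VCF). A forward Wright–Fisher
simulator with exact identity-by-descent tracking provides ground truth for
every stage, so the whole pipeline is testable without any external data.

## Worked example

Simulate offspring of full-sib matings (pedigree expectation F = 0.25), run
QC, detect ROH and estimate inbreeding:

```python
import numpy as np
import rohkit as rk
from rohkit.simulate import SimConfig, simulate_population

cfg = SimConfig(n_chromosomes=4, chromosome_length_bp=80_000_000,
                n_snps_per_chromosome=2000, effective_size=40,
                n_generations=0, sample_size=50,
                mating_design="full_sib_offspring", seed=7)
dataset, truth = simulate_population(cfg)
dataset, qc = rk.apply_qc(dataset)
print(f"after QC: {qc.retained_samples} samples, {qc.retained_markers} SNPs")

segments = rk.detect_roh(dataset)
records = rk.inbreeding_table(dataset, segments)
froh = np.array([r.f_roh for r in records])
ibd = np.array(list(truth.realized_ibd_fraction.values()))
print(f"detected ROH: {len(segments)}")
print(f"mean F_ROH  : {froh.mean():.3f}  (true IBD fraction {ibd.mean():.3f})")
print(f"r(F_ROH, F_HOM) = "
      f"{rk.pearson_correlation(froh, [r.f_hom for r in records]):.3f}")
```

prints

```
after QC: 50 samples, 7564 SNPs
detected ROH: 255
mean F_ROH  : 0.263  (true IBD fraction 0.263)
r(F_ROH, F_HOM) = 0.993
```

The detected mean F_ROH (0.263) matches the simulator's exact
identity-by-descent truth (0.263) and sits at the full-sib pedigree
expectation of 1/4; the two inbreeding estimators agree almost perfectly on
this mixed-inbreeding sample.

The full pipeline (QC → LD/Ne → ROH → inbreeding → islands) runs from one
YAML config or the command line:

```bash
rohkit simulate --out fixture --seed 7 --design full_sib_offspring
rohkit run-all --bfile fixture/sim --out results/
```

writing `qc_report.json`, `ld_decay.tsv`, `ne_trajectory.tsv`,
`roh_segments.tsv`, `roh_length_summary.tsv`, `inbreeding.tsv`,
`breed_summary.tsv`, per-population incidence tracks, `islands.tsv/.bed`
and the shared/specific island classification.

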