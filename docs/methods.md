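# Methods

This note documents the statistical procedures implemented in rohkit, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions that matter when comparing
output with other tools.

## Quality control

Filters are applied in a fixed order — autosome restriction, locus call rate,
minor allele frequency, Hardy–Weinberg equilibrium, sample call rate — with
allele frequencies computed from the loci surviving the earlier steps. All
call-rate and MAF comparisons are strict (`keep if value > threshold`, with
defaults 0.90, 0.90 and 0.01), and a locus is removed when its HWE p-value is
strictly below α = 0.001. The order follows the usual listing of these
criteria in array-QC protocols; because the locus filters are
per-locus-independent, only the final sample filter can interact with them,
and on data that already passed the filters a second application is a no-op.

The HWE test is the conditional exact test: with the allele counts fixed, the
probability of every possible heterozygote count is computed from the
hypergeometric-type kernel `P(het) ∝ 2^het · n! / (n_aa! het! n_bb!)`, and
the two-sided p-value sums all configurations no more probable than the one
observed. This matches the behaviour of standard QC software and is exact at
the small per-genotype counts where the χ² approximation fails. No
pre-installed library exposes this test, so it is implemented directly (in
log-space with `gammaln`) and verified against rational-arithmetic
enumeration in the tests.

Missing genotypes are **not** imputed. Downstream stages define their own
missing handling (pairwise-complete observations for LD; a per-window
missing allowance for ROH; per-locus exclusion for F_HOM).

## LD decay and effective population size

`r²` between two loci is the squared correlation of haplotype frequencies.
From unphased diploid genotypes all haplotypes are directly countable except
in double heterozygotes; their phase is resolved by
expectation–maximisation over the (B,B)-haplotype frequency, initialised at
linkage equilibrium, at most 1,000 iterations, convergence 1e-9. The EM is
run from three starts (linkage equilibrium and both feasible extremes of the
free frequency) and the solution with the highest multinomial likelihood is
kept, ties broken toward larger D²; this guards against the occasional
bimodality of the profile likelihood. The estimator is implemented
vectorised over all SNP pairs of a chromosome (9 indicator cross-products
give every 3×3 genotype table in one einsum), which is what makes
genome-wide decay curves cheap. No sample-size correction (e.g. subtracting
1/n) is applied by default, and pairs are pooled across chromosomes before
binning.

Decay is summarised in 20-kb distance classes `(k·20, (k+1)·20] kb` up to a
5-Mb cap, each eligible pair contributing to exactly one class. Effective
population size at `t` generations before sampling uses Sved's relation
rearranged,

    N_e(t) = (1 / 4c_t) (1 / E(r²|c_t) − 1),   c_t = 1/(2t) Morgans,

with physical distance mapped to `c` through a single genome-wide cM/Mb
ratio (default 1.415, the sheep-map value; `map_scale_from_totals` derives
it from genome totals). `E(r²|c_t)` is the mean of the 20-kb class containing
the target distance. The `t = 1/(2c)` mapping is used exactly, although it is
itself an approximation. Note that with the default 5-Mb pair cap the `t = 5`
target distance (≈ 7.06 Mb at 1.415 cM/Mb) falls outside the binned range and
is reported as missing rather than extrapolated; raise `ld_max_distance_bp`
to ~8 Mb if the most recent generations are needed.

## ROH detection

The scan follows the sliding-window procedure of the common detection tools:

1. windows of 50 consecutive SNPs; eligible when they contain ≤ 1
   heterozygous and ≤ 1 missing call;
2. each SNP is scored by the fraction of covering windows that are eligible,
   using only windows that actually exist (no padding at chromosome ends; a
   chromosome shorter than one window forms a single truncated window);
3. SNPs with score strictly above 0.05 are candidates; maximal consecutive
   candidate stretches are split at inter-SNP gaps > 500 kb;
4. surviving runs must span ≥ 500 kb, contain at least `l` SNPs and average
   ≥ 1 SNP per 50 kb over the run.

The minimum SNP count `l` defaults to the Lencz bound
`l = ⌈ln(α/(n_SNP·n_ind)) / ln(1 − h̄)⌉` with α = 0.05, the post-QC marker
total, the sample count and the mean per-locus heterozygosity; the ceiling
is required because rounding down would break the false-positive guarantee.
Run length is `end_bp − start_bp` (difference of terminal SNP positions, not
+1), the convention of the detection packages this scan mirrors; missing
SNPs inside a run count toward its SNP number but never as heterozygous.
The implementation is exactly equivalent to direct window enumeration — the
test suite and acceptance script verify segment-for-segment equality with a
brute-force oracle on hundreds of random instances.

One behaviour worth knowing: with unimputed missing data, a cluster of
missing calls spaced ~25 SNPs apart can make every window over a long
homozygous tract ineligible (≥ 2 missing each) and suppress detection. This
is inherent to the window method, not an implementation artifact; impute or
raise `max_missing_per_window` if missingness is high.

## Inbreeding coefficients

`F_ROH = ΣL_ROH / L_AUTO`, with `L_AUTO` the sum over chromosomes of
(max − min SNP position) of the post-QC map — i.e. data-dependent, not an
assembly constant. Per-chromosome values divide by the chromosome's own
span, so span-weighted per-chromosome values telescope exactly (to 1e-12)
to the genome-wide value.

`F_HOM = (O − E)/(L − E)` with `E = Σ_j [1 − 2p_j(1−p_j)·T_j/(T_j−1)]`
summed over the individual's called loci; `p_j` is the allele frequency and
`T_j` the called allele count at locus j. Frequencies are computed within
population by default (matching per-breed reporting), with a pooled option,
since cross-population frequency pooling inflates apparent homozygosity
(Wahlund effect). Sample standard deviations in the summary tables use the
n−1 denominator.

## ROH islands

Per population, each SNP's incidence is the fraction of individuals with a
ROH covering its position. The island threshold is the incidence of the SNP
at rank `⌈0.001·n⌉` of the descending distribution; all SNPs at or above it
(ties included) are candidates, and maximal map-consecutive candidate runs
form islands. The rank rule rather than a fixed percentage reproduces the
population-specific percentage thresholds such scans report. Shared vs
population-specific classification merges islands that overlap by ≥ 1 bp on
the same chromosome into clusters (transitively), independent of input
order. Gene annotation is pure interval intersection (≥ 1 bp) against
GFF3 `gene` features or 4+-column BED, with BED's 0-based half-open
coordinates converted to the package's 1-based inclusive convention.

## Synthetic data

The simulator is a discrete-generation diploid Wright–Fisher model with
ancestry tracking: haplotypes are mosaics of founder-haplotype segments,
gametes recombine as a Poisson crossover process at a constant cM/Mb rate
(no hotspots, matching the single genome-wide map ratio used elsewhere in
the package), and both parents of each offspring are drawn uniformly without
replacement. Because ancestry is exact, true IBD tracts — segments where an
individual's two haplotypes carry the same founder label — are emitted
exactly, not estimated. Founder haplotypes draw alleles from a
uniform(0.05, 0.95) frequency spectrum; mutation is omitted (the time scales
simulated are tens of generations). Mating designs `full_sib_offspring` and
`half_sib_offspring` produce sampled individuals whose pedigree inbreeding
expectation is 1/4 and 1/8 relative to the burn-in generation; with no
burn-in the founders are unrelated and those expectations are exact.

Default dimensions (26 chromosomes of 100 Mb, ~1 SNP per 50 kb, 1.415
cM/Mb, small missing rate) emulate an array-genotyped livestock population.
The validation runs in the tests and acceptance script deliberately use
fewer, shorter chromosomes (2–4 chromosomes of 50–80 Mb, 800–2,500 SNPs
each, populations of 30–200, burn-ins of up to ~80 generations): these sizes
preserve every quantity being checked — per-window statistics, LD at ≤ 5 Mb,
IBD tract lengths of recent ancestry — while keeping each simulation in
seconds. What the generator does **not** emulate: real site-frequency
spectra and ascertainment bias of array content, recombination hotspots,
mutation, gene conversion, genotyping error correlated along the array, and
realistic multi-breed demography. Passing the recovery tests therefore shows
the estimators are correct under their own model assumptions, not that real
data meet those assumptions.

`plant_sweep` overwrites a region in a chosen fraction of samples with one
shared homozygous haplotype — a deliberately crude stand-in for a completed
sweep that creates a known ROH-incidence plateau for island-calling tests.

## Numerical and interface conventions

- Genotypes are `{0, 1, 2, missing}` counting copies of `allele_b`; on PLINK
  .bed input `allele_b` is bim column 5 (A1), so 2-bit code `00` → 2, as in
  `plink --recode A`. VCF input counts ALT copies.
- Coordinates are 1-based with inclusive intervals (bim convention); BED
  output converts to 0-based half-open.
- Monomorphic loci make `r²` undefined: such pairs are signalled (scalar
  API) or dropped (decay binning), never coerced to 0 or 1.
- Degenerate inputs raise rather than return silently: empty genotype sets
  for heterozygosity, zero variance for correlations, `L = E` for F_HOM,
  chromosomes with a single SNP warn and contribute span 0.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configs give byte-identical
  outputs.

## Known limitations

- The window scan's sensitivity degrades with unimputed missingness (see
  above); the package intentionally ships no imputer.
- Sved-based N_e assumes the sampled r² is unbiased; with small samples the
  1/n inflation of r² biases N_e downward at large `t`. The recovery checks
  use 50–100 samples where the effect is within the stochastic tolerance.
- Island boundaries depend on tie handling at the rank threshold; different
  tools' exact island SNP counts can differ at ties even when the regions
  agree.
- `classify_shared` merges transitively, so one long island can chain
  otherwise-disjoint population islands into a single cluster.
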