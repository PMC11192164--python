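# Methods

This note records the statistical model behind `seedsource`, the
conventions chosen where the underlying quantities admit more than one
reasonable definition, what the synthetic-data generator does and does
not emulate, and the package's known limitations.

## Genotype input

The pipeline consumes hard genotypes: biallelic SNP records from a VCF
with a GT field, converted to alternate-allele dosages in {0, 1, 2} with
a missing sentinel. Multiallelic and non-SNP records are skipped and
counted. Low-coverage studies often carry genotype uncertainty as
genotype likelihoods instead; collapsing likelihoods to hard calls (or
estimating frequencies from likelihoods) is upstream preprocessing that
this package deliberately does not perform — the diversity/load/
combinatorics mathematics downstream is identical either way, operating
on per-SNP allele frequencies.

Missing genotypes are excluded per SNP from the frequency denominator:
p = (summed called dosages) / (2 × called individuals). No imputation is
attempted; this is the simplest unbiased frequency estimate and keeps
pools with different missingness patterns comparable. A SNP with zero
called alleles in a pool is dropped from that pool's diversity and load
computations.

## Genetic diversity

GD is the mean of He = 2p(1−p) over all usable SNPs of the panel, with
frequencies computed on the pooled individuals. Two conventions needed
fixing:

- **Monomorphic-in-pool SNPs are included** in the mean (contributing
  He = 0). GD is thus a per-genotyped-site average over a fixed panel,
  so pools of different sizes and compositions scored on the same panel
  are directly comparable; averaging over polymorphic-only sites would
  make the denominator pool-dependent. Ranking of pools is barely
  affected; absolute GD values scale with the monomorphic fraction.
- **No small-sample correction** (no 2n/(2n−1) factor). Candidate pools
  on a shared panel have similar sizes, and the uncorrected estimator is
  the classical He. The finite-sample bias factor (1 − 1/2n) is applied
  analytically in the simulator calibration tests instead.

Frequencies are alternate-allele (non-reference) frequencies, not minor
or ancestral/derived; He is symmetric in p ↔ 1−p so GD is unaffected,
and no ancestral polarization is attempted anywhere.

## Genetic load

GL = (Pn·fn)/(Ps·fs): the count of nonsynonymous SNPs segregating in
the pool times their mean alternate-allele frequency, over the same for
synonymous SNPs. Because Pn·fn is algebraically the summed frequency of
the class, the "count × mean" and "summed frequency" formulations are
identical. Conventions:

- SnpEff effect labels collapse to three classes. Nonsynonymous:
  missense variant, splice acceptor/donor/region variant, start lost,
  stop gained, stop lost. Synonymous: synonymous variant. Everything
  else (and any SNP absent from the annotation table) is OTHER and
  ignored by GL. Matching is case-insensitive and accepts space- or
  underscore-delimited labels. When several labels annotate one SNP the
  worst consequence wins (nonsynonymous > synonymous > other) — a
  deterministic precedence rule.
- **"Segregating" means polymorphic in the pool** (0 < p < 1). Sites
  fixed for the alternate allele are not segregating and are excluded
  from Pn/Ps; with unpolarized alternate-allele frequencies, counting
  alt-fixed sites would make load depend on reference-genome choice.
- GL is undefined (an explicit error, never NaN) when no synonymous SNP
  segregates in the pool. On realistic panels with hundreds of
  synonymous SNPs this cannot occur.

The selection score is the ratio GD:GL, defined for GL > 0. Higher means
more diversity per unit deleterious burden.

## Source-set optimization

All C(k, n) subsets of the k candidate populations are enumerated
(lexicographically, each subset sorted) and scored by pooling the
member populations' individuals. Exhaustive enumeration is deliberate:
the largest realistic instance, C(23, 5) = 33,649 pooled scorings, takes
seconds with the vectorised scorer (per-population allele counts are
precomputed once; each set is scored from summed counts, in blocks of
512 sets to bound memory). A configurable cap (default 10⁶ sets) guards
against accidentally astronomical requests.

Ranking is by GD:GL descending, ties broken lexicographically on
population IDs so output order is deterministic. The percentile of a set
is 100 × (#sets with ratio ≤ its ratio) / #sets — an inclusive
convention under which a unique best set sits at exactly the 100th
percentile and ties share the top of their block. Real-world vetting of
sets (access, cone crop, expert opinion) is represented only as
include/exclude lists in the run configuration.

The saturation curve reports the best and mean ratio over all sets at
each size n in a range, tracing the diminishing returns of adding
sources.

## Evolvability

Evolvability of seedling height is CV_G = √V_G / X̄. Without pedigree,
V_G = H²·V_P with a broad-sense heritability supplied externally
(default 0.3962, a common-garden estimate for one-year height).
Conventions:

- **Outlier removal**: single-pass Tukey fences at Q1 − 1.5·IQR and
  Q3 + 1.5·IQR (classic multiplier, configurable), quartiles by linear
  interpolation, applied per source within site to the observed alive
  heights. The filter is not idempotent (re-filtering recomputes the
  fences); it is applied exactly once. Filtering observed rather than
  mixed-model-fitted heights is a documented divergence from workflows
  that detrend plot effects first — fitted-height pipelines require the
  mixed-model machinery that is out of scope here.
- **Variance denominator** n − 1 throughout.
- **Pooled CV_G** is computed on the union of the filtered single-source
  heights and bootstrapped: each of B = 1000 replicates resamples
  N = 200 heights with replacement and computes CV_G; the replicate mean
  and standard deviation are reported. Fixing N makes the pooled
  estimate comparable to single-source estimates despite the pool's
  larger n (variance estimates, hence CV_G, are sample-size sensitive).
  The replicate SD uses denominator B − 1. Note the bootstrap mean is
  not algebraically √(H²·V_P_pooled)/X̄_pooled computed on the full
  pool; the two differ by resampling variability by design.
- **Fold gain** = pooled CV_G / smallest positive single-source CV_G,
  reported to one decimal — the "up to X× higher" summary.

Survivorship is descriptive: per-plot alive proportion (each record is
one planted seedling; the trial design plants 40 per plot, and an
explicit planted count can override the record count), then the mean of
plot proportions within source × site. Significance testing of
survival/height differences (GLMMs) is out of scope.

## Synthetic data

The generator exists so every stage is testable against known truth.

**Genotypes** follow the Balding–Nichols model: ancestral frequency
p̄ ~ Beta(a, b) per locus (default a = b = 0.5, a U-shaped spectrum
resembling a SNP panel's folded frequency distribution), population
frequency p ~ Beta(p̄(1−F)/F, (1−p̄)(1−F)/F) with per-population drift
F, dosages Binomial(2, p), uniform random missingness (default 5%).
The model was chosen for its closed-form moments: E[2p(1−p)] =
(1−F)·E_anc[2p̄(1−p̄)], which the tests verify by numeric integration,
with the (1 − 1/2n) finite-sample factor applied analytically.

Load differences are induced by the minimal mechanism GL responds to:
nonsynonymous frequencies in population i are updated as
p → max(p, min(λᵢ·p, 0.5)) with λᵢ ≥ 1. The update is exactly the
identity at λ = 1, monotone in λ (so populations ranked by λ rank
identically by expected GL), never decreases a frequency, and caps
inflation at 0.5 so deleterious variants stay at intermediate frequency
— drift load, not fixation. A naive cap `min(λp, 0.5)` would *lower*
frequencies above 0.5 even at λ = 1; the max(...) guard removes that
artifact.

Defaults emulate the candidate panel the analysis targets: 23
populations × 6 individuals; 3000 SNPs (1200 nonsynonymous, 1200
synonymous, 600 other) — a desk-scale panel, smaller than an exome
capture but large enough that per-population GD/GL estimates are stable;
F spread over 0.05–0.35 and λ over 1.0–1.4 so populations genuinely
differ in drift and load.

**Trials** mirror the monitoring design: single-source circular plots,
5 plots × 40 seedlings per source per site. A seedling survives with a
per-source probability (defaults spread over 0.75–0.95); surviving
heights are μ_s + g + e with g ~ N(0, V_G), e ~ N(0, V_E) and
V_G = H²/(1−H²)·V_E, so V_G/V_P equals the target heritability (default
0.3962) exactly in expectation. Defaults: V_E = 1.3 cm² (total V_P
≈ 2.15 cm²) and per-source means spread over 22–28 cm in a scrambled
order, matching the within-site spread observed in monitored plantings.
Plot membership is recorded but plots add no variance component — the
model the heights are drawn from is individual-level.

What the simulator does **not** emulate: linkage between loci, selection
(load arises by construction, not by fitness), genotype-likelihood
uncertainty, plot-level microenvironment effects, spatial structure, and
genotype-by-environment interaction. Passing tests therefore demonstrate
the pipeline's arithmetic and its statistical behaviour under the
assumed model, not robustness to those real-data complications.

## Determinism and numerics

Every stochastic stage consumes a NumPy `default_rng` seeded from a
single configured seed; identical config + seed gives byte-identical
pipeline output. Human-readable TSVs round to 3 decimals; the JSON
report keeps full precision. The vectorised set scorer and the direct
per-pool scorer follow the same operation order and agree to ~1e-12
relative tolerance (asserted in tests). Degenerate inputs (empty pools,
no usable SNPs, no segregating synonymous SNPs, non-positive means,
undefined loads) raise typed, message-bearing errors rather than
propagating NaN.

## Problem sizes used in the checks

The shipped tests and the reproduction script run the full candidate
search at C(23, 4) = 8855 sets on the 3000-SNP default panel,
Monte-Carlo calibration checks at 10⁴ loci, heritability recovery at
n = 800 seedlings, and bootstrap behaviour at B ∈ {100, 400, 1600} —
sizes at which the sampling error of each check is an order of magnitude
below its tolerance.

## Known limitations

- GD's absolute level depends on the panel's monomorphic fraction; only
  comparisons within a panel are meaningful.
- GL with unpolarized frequencies is a relative drift-load proxy;
  without ancestral states it cannot distinguish derived deleterious
  alleles from reference error.
- H² is a fixed input; errors in the external estimate scale all V_G
  and CV_G values by the same factor (rankings and fold gains with a
  common H² are unaffected).
- The bootstrap resamples heights i.i.d., ignoring plot clustering; its
  SD understates uncertainty if plot effects are strong.
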