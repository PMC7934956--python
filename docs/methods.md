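# Methods

This note documents the models behind `reefgxe`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical choices a maintainer would want to know about.

## The phenotype model

Each coral fragment carries an ordinal visual bleaching score in {0, 1, 2, 3}
at each survey timepoint (higher = more bleached; the package adopts this
orientation throughout). The fragment phenotype is the mean score over its
timepoints; the analysis phenotype is the **residual bleaching score**

    r_i = mean_score_i − site_mean(site of i),

with the site mean pooled over *all* retained fragments at the site (not a
leave-one-out mean). Residuals are computed on the untransformed mean scale;
the square-root transform is applied only as the response of the two-way
ANOVA, where it stabilizes the variance of ordinal means. Consequences worth
knowing:

- residuals sum to zero within every site by construction;
- the genotype-level phenotype (mean residual over a genotype's fragments
  across all sites) is a multi-site integrative measure of *relative* heat
  tolerance — a genotype can only look tolerant by out-performing its
  neighbours at the same sites;
- fragments flagged as early mortality (transplantation stress) are excluded
  before any of this; all available timepoints of the remaining fragments are
  used, including timepoints after partial mortality.

The G×E test is a two-way fixed-effects ANOVA with sequential (Type-I) sums
of squares in the order genotype, site, genotype:site. The design is balanced
except for one missing genotype×site cell and the randomly placed early
mortality, so term order is immaterial to three decimals; sequential SS keep
the decomposition exactly additive. Degenerate inputs (a single-level factor,
a constant response) raise rather than returning NaN statistics.

The bleaching–mortality analysis uses a two-sided rank-sum test (normal
approximation with continuity correction at these sample sizes) of fragment
mean score between died and survived fragments, and a linear regression of
per-combination mortality fraction on mean score restricted to combinations
without complete mortality — combinations where everything died carry no
gradient information and are reported separately as a fraction.

## Thermal summaries

Hourly per-site series are summarized by mean, s.d., mean daily range (days
with fewer than 20 of 24 observations are excluded from daily statistics
only), overall maximum, and counts of hours strictly above each threshold in
{30.5, 31, 32, 33} °C. Degree heating weeks accumulate, over hourly
observations with T ≥ MMM + 1 (MMM = 28.7 °C, threshold 29.7 °C),

    hotspot mode (default):  (T − MMM) / 168        °C-weeks
    excess mode:             (T − threshold) / 168

The hotspot rule is the NOAA convention and is the default because
season-scale magnitudes of 10–14 °C-weeks over ~15 weeks arise naturally from
degree-weighted accumulation; the excess rule is exposed as a config switch
since logger-based studies sometimes accumulate only the excess above the
stress threshold. DHW is additive over disjoint windows and invariant to
adding sub-threshold observations; both properties are tested. Timestamps
are taken at face value (no timezone conversion); day boundaries are
calendar days of the given clock.

The cross-site PCA decomposes the sites × days matrix of daily mean
temperatures (days restricted to common coverage; sites missing more than
20% of candidate days are excluded with a notice). Columns are centred per
day, so components describe how sites deviate from the fleet-wide daily
pattern.

## Dosage and screening

A genotype-probability triplet (P_aa, P_ab, P_bb) becomes the expected
secondary-allele count `d = P_ab + 2·P_bb ∈ [0, 2]`, which propagates calling
uncertainty from low/variable read depth into one number per cell without
hard-calling. Uninformative cells (no sequencing evidence) are missing.
Screening regresses the genotype-level mean residual on dosage per locus,
using the two-sided t-test on the correlation; loci with any missing
genotype or zero dosage variance are excluded (counts reported). Retention
is on p alone, so protective and susceptible alleles are both kept; the full
signed r vector is preserved for enrichment. Note that at n = 10 genotypes
p < 0.01 corresponds to |r| ≳ 0.765, so a causal locus realizing r = 0.74 is
*not* retained — the screen is a hard gate on evidence, not on effect size.

## The ensemble model

A random forest (500 trees, one candidate predictor per split) regresses
genotype-level residuals on retained dosages. mtry = 1 forces every split to
consider a single randomly chosen locus, keeping the ensemble close to a sum
of univariate effects — the appropriate bias at n = 10 samples with dozens of
mutually correlated predictors. 500 trees is enough that the resampled skill
moves < 0.01 between tree-count doublings at the default problem size. Trees
are grown to purity (no minimum node size): with 5-sample training folds any
nontrivial minimum leaf size makes trees unsplittable and predictions
constant, which is uninformative.

Skill is estimated by 2-fold cross-validation repeated 20 times: each repeat
randomly splits the samples 5/5 (no stratification — none is possible on a
continuous response at n = 10), trains on each half and predicts the other,
recording **R² = squared Pearson correlation between held-out predictions
and observations** per fold (40 values). This definition is stated explicitly
because R² conventions diverge for non-nested predictions; 1 − SSE/SST can
be negative here and is not used. A held-out fold with constant predictions
scores 0 and is flagged. A consequence of the correlation definition worth
remembering when reading null results: for 5-point folds the squared
correlation of two *independent* vectors has expectation 1/(n−1) = 0.25, so
"no skill" sits near 0.25, not 0.

### Missing-data robustness

The no-information dosage of a locus is the dosage implied by the genotype
prior alone: 2·(estimated secondary-allele frequency) under the default
frequency prior (the posterior a frequency-prior caller collapses to with no
reads), or 1.0 under a flat prior (config switch). The robustness procedure
replaces a random fraction f of the model's loci — for all samples — with
that value, predicts with the already-fitted forest, and records the squared
correlation with the observed phenotypes; 100 replicates per fraction,
summarized as mean ± sd. The curve is non-increasing in f in expectation.
Fractions are configurable with 0.5 as the reference point.

### Novel samples

Prediction for samples outside the training set requires at least 30 called
model loci (slightly more than half of 58); remaining missing cells are
imputed with the no-information dosage. An optional one-sample-per-reef
seeded subsample reduces bias toward heavily sequenced reefs. Downstream,
a one-way ANOVA compares predicted residuals between regions and a
Kolmogorov–Smirnov test compares their distribution with the training
phenotypes; an external physiological series (e.g. relative fv/fm decline)
can be regressed on predictions for validation.

## Enrichment

Every locus in the screened universe keeps its signed correlation
coefficient; each annotation category is tested by a one-sided Mann–Whitney U
of member loci against non-members, direction of interest = enrichment toward
high (bleaching-associated) correlations, with the opposite tail reported as
a separate column. Ties take midranks. Benjamini–Hochberg adjustment is
applied within each GO namespace; categories smaller than 5 loci or covering
more than 10% of the universe are excluded. Categories are tested flat:
GO-hierarchy propagation and category clustering are deliberately out of
scope — they belong to the hierarchy-aware tools, and a flat test keeps the
procedure transparent and exactly checkable against the rank-sum closed form.

## The synthetic-data generator

The generator emulates the statistical structure of a multi-site reciprocal
transplant observed through an ordinal bleaching scale and a low-coverage
RAD-seq panel. Defaults are the study dimensions: 10 genotypes × 8 sites ×
10 replicate fragments with one genotype×site combination never outplanted
(79 combinations), 3 survey timepoints, 122 early-mortality fragments
(leaving 668), 13,337 loci of which 58 are causal with target dosage–
phenotype correlations uniform in (0.73, 0.89).

**Survey.** Latent fragment severity = genotype effect + site effect +
interaction + fragment noise, with variance components (0.04, 0.20, 0.05,
1.00 latent units²) chosen so the two-way ANOVA F ratios land in the regime
seen in multi-site field data — site effects dominant (F ≈ 14–17), a clear
genotype effect (F ≈ 3–5), a modest but significant interaction (F ≈ 1.6).
Effects are centred and rescaled to exact mean-square so recovery tests are
well-posed at small factor counts; interactions are double-centred. Each
timepoint adds N(0, 0.25) observation noise and the sum is cut into {0,…,3}
at the quartiles of the marginal latent distribution (configurable
thresholds). Survival through the final census is Bernoulli with logistic
link on latent severity (slope 1.5, intercept −0.5: more bleached fragments
die more often); early mortality is assigned uniformly at random, reflecting
transplantation stress unrelated to heat tolerance.

**Genotypes.** One sample per genotype. Null loci draw Hardy–Weinberg
genotypes at a per-locus MAF uniform in (0.10, 0.45). Read depth is
gamma-Poisson (mean 20, shape 2 — the regime of depth-filtered RAD data) and
the probability triplet mixes a point mass on the true genotype with the HWE
prior at weight w = d/(d+1), so deep cells are near-one-hot and zero-depth
cells are pure prior (uninformative). Causal loci are built by thresholding
a latent variable correlated with the phenotype at HWE quantiles and are
accepted only when the *realized* dosage correlation lands in the target
band (batched rejection, closest candidate kept as fallback). Because the
study's 0.73–0.89 band describes correlations realized against the observed
phenotype (the loci were selected on it), the pipeline anchors causal loci
to the observed genotype-mean residuals; anchoring to the noiseless true
residuals is the default for direct generator use and shifts realized
correlations down by the phenotype measurement error.

**Temperature.** Baseline + annual sinusoid + diel sinusoid + white noise
per site, hourly, with optional gap schedules; per-site parameters vary
mildly around a 29.5 °C summer baseline.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage between loci (locus noise is
independent given the phenotype, so ensemble averaging is more effective
than on structured genomes; measured robustness to missing loci is
correspondingly optimistic by a few points), population structure,
symbiont-community effects, spatial or temporal autocorrelation of scores
within sites, and non-random early mortality. The generator's clean
conditional independence is the main reason its in-sample fit (squared
correlation ≈ 0.99) exceeds what messy field panels give.

**Randomness.** Every stage draws from an independent child stream of one
master seed (`SeedSequence(seed, spawn_key=(stage,))` with fixed stage
indices), so the survey, genotype panel, temperature series, fold splits,
tree seeds and masking replicates are individually reproducible from the
seed alone, and any stage can be re-run in isolation.

## Problem sizes

The test suite and the benchmark script run the matched-structure problem
(10 genotypes, 58 loci) with 5 generator seeds, 40 CV fits per seed and 100
robustness replicates; calibration properties (type-I error of the
interaction test, null screening rate) use 200 simulated datasets of a
6×4×5 design and a 10,000-locus null panel respectively. These sizes give
3σ binomial bands around nominal rates and seed-averaged skill estimates
stable to ~0.02.

## Known limitations

- The ordinal scale's semantics (which end is "fully bleached") are a
  convention here; flipping it flips residual signs everywhere.
- The t-test p-values in the screen assume independent genotypes; kinship
  between samples would inflate the retained set.
- The permutation-null CV skill sits near the 5-point-fold chance level of
  0.25 (see the R² definition note above); comparisons of CV skill between
  models should subtract that floor rather than treating 0 as "no skill".
- Robustness means are reported on the squared-correlation scale; they are
  not comparable to 1 − SSE/SST numbers from other pipelines.
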