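# Methods

## Model and sampler

The core model regresses a continuous phenotype on a chosen set of
predictors with indicator-based (spike-and-slab) variable selection:

y_i = α + Σ_l I_l β_l x_il + e_i, e_i ~ N(0, σ²).

The indicator enters multiplicatively (Kuo–Mallick composition) rather
than through a spike-variance mixture (SSVS). This choice makes the
"non-indicator" models exact special cases — fixing I_l ≡ 1 gives
ordinary Bayesian regression, I_l ≡ 0 removes a predictor — and keeps the
prior on β independent of I. To preserve mixing, the coefficient of an
excluded predictor is refreshed from its prior at every sweep, so that
when the indicator is next proposed the coefficient is not stuck at a
stale value.

Priors and defaults:

| parameter | prior | default | rationale |
|---|---|---|---|
| α | N(0, 1) | — | weakly informative on a phenotype of roughly unit scale |
| β_l | N(0, τ²_type) | τ² ~ IG(2, 1) | prior mean 1 for τ², per marker type; a fixed τ² may be supplied instead |
| I_l | per-type regime | fixed π = 0.1 (markers), 0.01 (genes) | sparse prior model sizes on typical panels |
| π (vague regime) | Uniform(0, 1) | — | Beta(1,1); updated from its conjugate Beta full conditional |
| σ² | IG(0.01, 0.01) | — | near-scale-invariant residual prior |

One Gibbs sweep updates, in order: α (conjugate normal), then for each
column its indicator given the current coefficient (Bernoulli from the
likelihood ratio) followed by its coefficient (conjugate normal when
included, prior draw when excluded), then π per uniform-regime type
(Beta), τ² per hierarchical type (inverse-Gamma over all coefficients of
the type, included or not — valid because excluded coefficients are prior
draws), and finally σ² (inverse-Gamma). The running residual vector is
recomputed from scratch every 256 sweeps to cap floating-point drift. The
inner loop is compiled with numba; a pure-Python fallback with the same
random stream exists but is only practical for tiny problems.

Defaults for a standalone fit are 2 chains × 12,000 iterations with 2,000
burn-in and thinning 2; cross-validation strategies default to 4,000
iterations (burn-in 1,000) per fold, which on pre-selected panels of ≤100
columns reproduces inclusion probabilities across independent seeds to
within ±0.03. A seed is mandatory; chains derive their own seeds from it.

Posterior predictions are posterior means of α + Σ I_l β_l x_il, computed
with the training-set standardization reapplied to new lines. Deviance is
the posterior mean of −2 log N(y | μ(draw), σ²(draw)) (posterior mean
deviance, not deviance at posterior means).

## Pre-selection

* Markers are ranked by the absolute pooled-variance two-sample
  t-statistic between genotype groups (a Welch variant is available by
  flag). Markers with fewer than two lines in either group are skipped
  and logged.
* Genes are ranked by absolute Pearson correlation with the phenotype;
  the top-fraction cut uses ceiling rounding (so 10% of 28,395 genes is
  2,840 and 5% of 941 markers is 48). Zero-variance genes score 0 and
  rank last. Ties break by input column order for reproducibility.
* Common-subset selection intersects the top-fraction sets of the k
  learning-set rankings plus the all-data ranking, ordering survivors by
  the all-data ranking. Because the all-data list touches each held-out
  fold, results using this path are explicitly flagged
  (`used_full_data_ranking`) rather than silently treated as leak-free.
* The bootstrap stability profile records, per gene, the mean and sd of
  its phenotype correlation over B = 100 resamples of m = ⌈0.77·n⌉ lines
  drawn with replacement.
* Supervised PCA computes principal components of the
  correlation-filtered expression submatrix (centred; scaling optional)
  and uses the top component scores as predictors. Component signs follow
  a deterministic convention (largest-magnitude loading positive);
  held-out lines are projected with the training means and loadings.

## Evaluation

Folds are near-equal random partitions re-drawn (up to 100 times) until
every fold's phenotype deciles sit within 0.25 × interquartile range of
the full-sample deciles; failing that, the best partition is returned
with a warning. The out-data metric is a single pooled correlation over
the concatenated held-out predictions of all k folds (per-fold deviances
are kept alongside); in-data correlations are averaged over the k
training fits. An intercept-only fit has no in-data correlation; it is
recorded as 0 with a warning. The permutation test re-runs the entire
pipeline — pre-selection included — on phenotype values permuted across
lines, with p = (1 + #{null ≥ observed}) / (n_perm + 1).

## Relevance and enrichment

Per-predictor joint relevance is the posterior mean of I·|β|; marker
columns are additionally multiplied by the column's empirical genotype
variance p̂(1−p̂) ("weighted genetic variation"). This operationalization
is isolated in one function so an alternative weighting can be swapped
in. Gene-set summaries report the mean weighted genetic variation over a
set's marker members and the summed (optionally mean) weighted
coefficient over its expression members; members with zero relevance are
included in the averages. No parametric enrichment p-value is defined;
significance against random sets is available through resampling in the
test suite. The two-coefficient genotype parameterization (and the
associated "absolute difference of coefficients" relevance) is not
implemented; genotypes are coded 0/1 with a single coefficient per marker.

## Synthetic data generator

The generator emulates a RIL panel: genotypes follow a two-state Markov
chain along each chromosome with switch probability R = 2r/(1+2r) (the
Haldane–Waddington limit of repeated selfing), chromosomes independent,
allele frequencies 1/2. The default map spreads 941 markers over 20
chromosomes with r = 0.1 between neighbours — moderate linkage typical of
a mid-density plant map; the default population is 260 lines with 2,000
genes (a desk-scale stand-in for a 28,395-gene panel). A configurable
fraction (default 0.3) of genes is cis-driven by one marker
(effect 1.0, noise sd 1.0, giving a cis correlation ≈ 0.45); the rest are
Gaussian noise. Phenotypes are sparse additive functions of a few markers
(effects ±2 on the 0/1 coding, so each contributes ≈ unit genetic sd) and
a few standardized gene expressions (effects ±1), plus Gaussian noise
rescaled so the realized genetic-variance share equals the requested
heritability exactly. The explicit pedigree simulator (F1 followed by ≥20
selfing generations) lives in the test suite as an independent oracle for
the Markov-chain shortcut.

What the generator does **not** model: epistasis and dominance (RILs are
homozygous), genotyping error, missing data, trans-eQTL networks,
segregation distortion, heavy-tailed or skewed phenotypes, and
correlation between multiple phenotypes (a second phenotype is produced
by an independent call with its own QTL set). Passing recovery tests on
these data therefore demonstrate correctness of the machinery under the
model's own assumptions, not robustness to the realities of a particular
field experiment.

## Numerical choices and degenerate inputs

* Fractional top-k cuts use ceiling rounding; ranking ties break by
  column order.
* Fixed inclusion probabilities of exactly 0 or 1 short-circuit the
  Bernoulli update (no log-odds evaluation); logistic arguments are
  clamped at ±35 before exponentiation.
* A phenotype with zero variance, an empty line intersection between data
  sources, or a selection naming an unknown id all raise immediately with
  the offending name.
* Near-constant vectors (equal up to ~1 ulp) are treated as zero-variance
  in correlation computations.
* Prior-only sampling clips inverse-Gamma underflow so σ² draws stay
  finite (shape 0.01 is astronomically heavy-tailed).

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run the pipeline at desk
scale: marker panels of 300–941, gene panels of 600–2,000, populations of
60–260 lines, 10 simulation seeds for averaged claims, and 200
calibration replicates (at 300 MCMC iterations and 19 permutations each)
for the permutation-test null. These sizes were chosen so each averaged
quantity has Monte-Carlo error comfortably inside its assertion band:
e.g. the prior model-size checks use ≥40,000 prior draws (standard error
< 0.1 of a predictor), and the sampler-vs-enumeration check uses 2 × 35,000
retained draws against an oracle integrating σ² on a 400-point log grid.

## Known limitations

* Single-site Gibbs scans mix slowly when predictors are extremely
  collinear; PIPs then spread across proxies (see the worked example in
  the README). This is a property of the model class, reported honestly
  by the PIPs, not a sampler defect.
* The Uniform(0,1) inclusion regime shares one π per marker type; a
  per-predictor Beta hierarchy is not implemented.
* Gaussian errors only; skewed phenotypes are outside scope.
* Interaction (epistatic) effects are not modeled.
* The common-subset selection path is flagged, not corrected, for its
  use-of-data-twice defect; constructing extrapolation-safe learning/test
  splits in high dimensions is an open problem and not attempted.
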