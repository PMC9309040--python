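# Methods

## Data model

The sampling unit is the *patch*: one discrete piece of ephemeral habitat
evaluated for nematode presence. Collection records carry the sampling
hierarchy (locality → site/tree → quadrat → patch), a substrate category,
and the set of species observed; bait and exclosure records carry the
experimental design cell and a recovery flag. Presence is the only
within-patch quantity modelled — abundance is deliberately outside the data
model, since field isolation protocols make per-patch counts incomparable.

Validation happens at construction: a nonempty species set forces the
nematode-presence flag, unrecovered baits cannot carry observations, and
temperatures must be finite and within −10…60 °C. Species names are
normalized (whitespace collapsed, one-letter genus abbreviations
upper-cased) with no fuzzy matching, so tabulated counts remain auditable
against the raw CSV. Lost or damaged samples are simply absent rows: all
analysis denominators are recomputed from the records present, never from
nominal design sizes.

## Richness estimation

Chao2 uses only the incidence frequencies Y_i and the unit count m. The
classic form applies when duplicates exist (Q2 > 0); at Q2 = 0 the
bias-corrected form replaces Q1²/(2Q2), avoiding the division by zero while
retaining the estimator-family convention. The point estimate never falls
below S_obs, and equals it exactly when Q1 = 0.

Rarefaction is the exact combinatorial expectation over unit subsets;
binomial coefficients are evaluated through log-gamma so large m cannot
overflow, and C(a, t) is taken as 0 when a < t. t = 0 is accepted and
returns 0 (the analytic endpoint). Extrapolation uses the standard
incidence-based form driven by Q̂0 and Q1; when Q1 = 0 the curve is flat at
S_obs, and the interpolated and extrapolated branches agree at t = m by
construction. The default knot grid is 40 evenly spaced integers from 1 to
2m, plus the endpoints 0 and m.

The bootstrap resamples whole sampling units (matrix columns) with
replacement — preserving within-unit co-occurrence — with B = 200 by
default, percentile 95% intervals and the replicate standard deviation as
the SE. Replicates drop species that lose all incidences. Because the
percentile interval is anchored to resampled data, the reported interval is
clipped to bracket the point estimate. A single sampling unit yields a
warned, zero-width interval. When only frequencies (not a matrix) are
available, a maximally nested matrix with the same marginals is used; the
Chao2 statistic and its unit bootstrap depend on the data only through the
marginals, so this is exact for them, but it does *not* carry co-occurrence
information.

On the packaged island assemblage (225 units, Y = 152…2) the bootstrap SE
is ≈ 0.3 species, dominated by occasional dropout of the rarest species —
the same order as the survey's printed interval, whose construction method
is not recorded; the acceptance check therefore constrains the CI
half-width to a sanity band rather than an exact value.

## Zero-class Poisson colonization

λ̂ = −ln(1 − p_occ) is the method-of-moments/ML estimator of a Poisson mean
from its zero class. Saturation (every patch occupied) raises an error
rather than returning λ = ∞, forcing callers to handle it explicitly. The
95% CI transforms an exact Clopper–Pearson interval on p_occ; the map is
monotone, so coverage is inherited. Class probabilities are computed at
full precision and rounded only for display (2 dp), matching how such
quantities are conventionally reported.

The estimator assumes homogeneous λ across patches. The simulation module
quantifies what patchiness does to it: with lognormal site/quadrat random
effects the zero class is inflated (Jensen's inequality) and λ̂ is biased
downward; the test suite checks both the sign and the magnitude of this
bias against a direct Monte-Carlo evaluation of the mixed model. Estimates
from strongly clustered surveys should therefore be read as lower bounds on
the colonization intensity of occupied areas.

## Co-occurrence and exact tests

The pairwise test builds the 2×2 presence table and reports the
independence expectation n·(a/n)·(b/n) plus an exact conditional p-value.
The two-sided rule is probability ordering: the p-value sums the null
(multivariate hypergeometric) probabilities of all tables with the observed
margins whose probability does not exceed the observed table's, with a
1e−9 relative tolerance absorbing float ties. The same enumeration handles
2×k tables (bait-type distributions); when the candidate-table count
exceeds a configurable budget (default 5·10⁵) a seeded Monte-Carlo
estimate with add-one correction (count+1)/(n+1) takes over. For 2×2
tables the implementation agrees with the standard two-sided Fisher test
to machine precision (cross-checked in the tests, not delegated).

## Analyses of deviance

With one categorical factor and grouped binomial outcomes, per-level rate
MLEs make the alternative the saturated model, so the analysis of deviance
reduces to a closed form (residual deviance 0, null deviance = the LRT
statistic). This equals the deviance difference of an iteratively fitted
dummy-coded logistic regression — verified against an independent GLM
implementation in the tests — while avoiding convergence concerns at
boundary counts (0·ln 0 = 0 terms). Levels with zero trials are dropped
with a warning and reduce the degrees of freedom. Only recovered baits
enter experimental analyses. P-values are reported raw; no
multiple-testing correction is applied, and reports say so.

The cross-taxon rate correlation regresses, per bait type, the fraction of
recovered baits colonized by the focal genus on the fraction colonized
*only* by other nematodes (baits holding both taxa are excluded from x, so
the two rates are not trivially coupled). The regression is unweighted
across types — bait counts per type are nearly equal by design — and the
p-value is the slope t-test with k−2 df.

## Synthetic data

The generators emulate the three study designs with their published sizes
as defaults: the hierarchical flower survey (4 trees × 3 quadrats × 4
flowers with one tree at 2 quadrats → 44 patches), the bait experiment
(7 sites × 5 arrays × 6 types → 210 baits, loss probability 29/210), and
the exclosure experiment (6 sites × 4 replicates × 6 treatments → 144
baits, loss 1/144).

Colonization counts are K ~ Poisson(λ_s·u) with
u = exp(ε_site + ε_quadrat − σ_s²/2); the two random-effect levels each
have sd σ_s/√2 on the log scale so the total log-variance is σ_s² and
E[u] = 1, keeping the marginal mean at λ_s. Lognormal multiplicative
effects were chosen as the simplest mean-correctable heterogeneity model
consistent with strongly patchy occupancy; no quantitative field estimate
of σ exists, so the defaults (0.3 for the ubiquitous species, 1.5 for the
patchy ones) are illustrative and flagged as such. Default intensities put
the common species at λ = 1.08 and rarer species lower. Bait and
exclosure colonization are independent Bernoulli draws per taxon group
with type/treatment-specific probabilities whose defaults carry the
qualitative structure of the experiments (ground contact > dish, peptone >
flower slurry; focal-genus probability zero behind mesh ≤ 1 mm); overall
rates are in the observed range but per-cell values are illustrative.

True K values are emitted in a sidecar table keyed by sample and species —
never inside the records — so analysis code cannot read the truth. All
randomness flows from one integer seed through a single PRNG
(`numpy.random.Generator`, PCG64); identical configs give byte-identical
CSV output across runs and platforms.

What the simulations do **not** emulate: explicit spatial coordinates or
dispersal kernels, within-patch population dynamics, seasonal turnover, or
correlated colonization between species. Passing parameter-recovery tests
therefore shows the estimators are correct under the stated sampling
models, not that real surveys satisfy those models — the heterogeneity
experiments exist precisely to show the direction and size of the error
when they do not.

## Packaged survey inputs

The per-sample records behind the published summary tables are not
machine-readable, so `datasets` packages the printed per-species counts
and rebuilds record-level fixtures where needed: observations are dealt
round-robin over samples, making every per-species and per-subset marginal
exact while the within-sample co-occurrence pattern is an explicit
synthetic reconstruction. Analyses that depend only on marginals
(incidence frequencies, totals, Chao2) are exact on these fixtures; the
flower-survey fixture additionally reproduces the published 2×2
co-occurrence table exactly.

## Problem sizes and numerical choices

Simulation-based tests use replicate counts chosen to make their Monte
Carlo error small relative to the tested effect: 5000 null datasets for
type-I calibration, 100 replicates at n = 10⁵ for λ recovery, 200 runs for
power checks, 250 datasets × 120 bootstrap replicates for CI coverage, and
exhaustive enumeration wherever m ≤ 12 makes it exact. Tolerances are
3 (occasionally 4) Monte-Carlo standard errors, 1e−12 for quantities with
exact oracles. JSON output serializes floats at 12 significant digits with
sorted keys so identical runs produce identical bytes.

## Known limitations

* No site-level random effects in the deviance analyses (single-factor
  models only); heterogeneity across sites inflates their type-I error on
  clustered data.
* The zero-class λ estimator is a lower bound under patch heterogeneity.
* Chao2 is itself a lower-bound estimator; its bootstrap interval can
  undercover when many species sit at the detection edge.
* The record model is presence-only; abundance-based estimators (Chao1,
  coverage-based rarefaction, Hill numbers of order q ≠ 0) are out of
  scope.
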