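# Methods

## The model

Let Y₁ (anemia) and Y₂ (undernutrition) be binary outcomes for one child
with covariate vector x. Each margin is an ordinary logistic regression,
π_j(x) = expit(xᵀβ_j), and the joint law of (Y₁, Y₂) given x is the unique
bivariate Bernoulli distribution with those margins and a fixed
cross-product ratio

ψ = p₁₁p₀₀ / (p₁₀p₀₁),

the Plackett (global odds ratio) family. Its (1,1) cell has the closed form

p₁₁ = [S − √(S² − 4ψ(ψ−1)π₁π₂)] / (2(ψ−1)),  S = 1 + (π₁+π₂)(ψ−1),

for ψ ≠ 1 and p₁₁ = π₁π₂ at independence. The implementation rationalises
the root to p₁₁ = 2ψπ₁π₂ / (S + √(S²−4ψ(ψ−1)π₁π₂)), which is stable
through ψ → 1 and needs no branch; cells are clamped to the Fréchet box
[max(0, π₁+π₂−1), min(π₁, π₂)] against last-bit rounding. Partial
derivatives of p₁₁ come from implicit differentiation of p₁₁p₀₀ = ψp₁₀p₀₁.

ψ is constant across covariate patterns by default: the scientific claim
being modelled is a single population-level dependence between the two
conditions, with covariates acting on the margins. A hook (`psi_design`)
allows covariates on log ψ but is off by default.

### Estimation

The full parameter is θ = (β₁, β₂, log ψ); log ψ enforces ψ > 0. The
weighted joint log-likelihood Σᵢ wᵢ log p_cell(yᵢ | xᵢ) is maximised by
Newton ascent: analytic score, central-difference Hessian of that score,
step-halving to guarantee monotone likelihood ascent, and a steepest-ascent
fallback when the Newton direction is not an ascent direction. Starting
values are two univariate logistic IRLS fits for the margins plus the log
empirical 2×2 odds ratio (0.5 continuity-corrected if a cell is empty) —
at an intercept-only model this start is already the MLE and the iteration
detects stationarity immediately. Convergence requires a relative
log-likelihood change below 1e−10 and a maximum absolute score below 1e−6;
default iteration cap 100, with a warning (not an error) on
non-convergence, and a separation warning when any |β̂| exceeds 15.
Cell probabilities are clipped to [1e−12, 1−1e−12] inside the likelihood
and floored at 1e−300 (with a warning) before taking logs.

The covariance is the inverse negative Hessian at the optimum. Sampling
weights are normalised to mean one and treated as frequency weights
(pseudo-likelihood), so reported variances are model-based; design-based
two-stage survey variance estimation is deliberately out of scope and the
fit output carries a note saying so. AORs are exp(β̂) with Wald 95%
intervals and two-sided Wald p-values, unadjusted for multiplicity.

## Composite undernutrition index

PCA is computed on the *correlation* matrix of (HAZ, WAZ, WHZ) — its
eigenvalues sum to 3 — not the covariance matrix, so the index is invariant
to common rescaling of the z-scores. Loading columns are sign-normalised so
the largest-magnitude entry is positive, which makes all three PC1
loadings positive for a positively correlated triplet. The composite score
is the raw PC1-weighted sum of the z-scores, and the −2 cutoff is applied
to that raw sum (strict inequality; a score of exactly −2 is nourished),
matching the construction the package emulates, even though the raw sum
has standard deviation √λ₁ ≈ 1.41 rather than 1. `standardize=True`
rescales to unit variance first for the statistically conventional
variant; with the default configuration that choice moves the prevalence
of the composite indicator substantially (the cutoff then sits at −2
standard deviations of the composite rather than −2 z-score-sum units), so
the two variants are not interchangeable and the raw rule is the default.
When PC1 explains less than 50% of total variance the pipeline warns that
a single composite is questionable but continues. Rows missing any z-score
are dropped and counted (complete-case).

## Exploratory tables

The joint 2×2 table reports the dependence odds ratio twice: from raw
counts, and from cell probabilities rounded to `rounding_digits` (default
3) decimals first. Published tables print rounded probabilities, and the
two variants differ visibly at n ≈ 3000 (1.722 vs 1.729 for the reference
counts); both are reported with a note rather than silently choosing one.
Marginals are always derived from the joint cells; user-supplied marginals
that disagree are logged, since published tables occasionally disagree
with their own margins. Chi-square screening is the Pearson statistic
without continuity correction (this reproduces the published twin-row
p = 0.003); expected cells below 1 set a flag rather than aborting.
Frequency percentages use largest-remainder rounding to 1 dp so each
variable sums to exactly 100.0.

## Goodness of fit

The correct classification rate for a bivariate outcome is not uniquely
defined, and the emulated analysis does not state its rule. The default
here is the natural joint rule: predict the argmax of the four fitted cell
probabilities, and count a row correct when both outcomes match. Ties are
broken deterministically in the fixed cell order (p₀₀, p₁₀, p₀₁, p₁₁).
The alternative `marginal_threshold` rule predicts each margin by
π̂_j ≥ 0.5; under it the joint CCR can never exceed either marginal CCR.
Both marginal CCRs are reported under either rule. Note that with an
intercept-only (or weakly informative) model the joint argmax prediction
is constant and the joint CCR equals the modal joint cell frequency — high
CCR values therefore mostly reflect unbalanced margins, not discrimination.

## Synthetic data generator

The generator emulates the study conditions the package was built around,
and those conditions are its defaults, fixed once:

- **n = 3206** children (the published weighted sample).
- **Z-scores** are drawn multivariate normal with unit variances, target
  correlations r(HAZ,WAZ) = 0.42, r(HAZ,WHZ) = 0.44, r(WAZ,WHZ) = 0.62,
  and means (−1.0, −0.5, 0.0). The means were chosen once so that (a) they
  are realistic for the surveyed population — height-for-age worst,
  weight-for-height near reference — and (b) under the Gaussian model the
  raw composite rule P(lᵀZ < −2) ≈ 0.202, matching the published
  undernutrition prevalence of 20.5%. Z-scores are simulated directly;
  computing them from raw anthropometry via growth-standard LMS tables is
  out of scope because the analysis consumes z-scores only.
- **Covariates** (residence, water source, maternal anemia, twin status,
  child age band, sex, birth size) are sampled independently from the
  published marginal frequencies; only marginals are published, so no
  dependence between covariates is emulated.
- **Outcomes** follow the bivariate model itself: marginal logits built
  from the published adjusted odds ratios, dependence ψ = 1.729, one
  categorical draw per child from the four Plackett cells. Intercepts are
  calibrated at config construction by exact enumeration over the
  covariate-pattern distribution so the population-average prevalences
  equal the published 46.2% (anemia) and 20.5% (undernutrition) exactly in
  expectation.
- **Anemia** is generated directly as the binary outcome by default. An
  optional hemoglobin mode instead draws altitude-adjusted hemoglobin from
  truncated normals on either side of a configurable cutoff (default
  11.0 g/dL — an implementation choice; the emulated analysis does not
  state its cutoff) consistent with the drawn indicator.
- **Weights** are 1 (uniform) by default, or gamma(shape, rate) draws for
  exercising the weighted paths.
- **Seeding**: one master seed; per-stage sub-streams derived with
  `SeedSequence.spawn`, so identical configs give byte-identical CSVs.

What the generator does *not* emulate, and hence what passing tests do not
establish about real data: two-stage cluster sampling geometry (weights
are stand-ins, not design weights), dependence among covariates,
missingness patterns, and any coupling between the simulated z-scores and
the binary undernutrition outcome — the z-scores exercise the index
module, the binary outcomes exercise the model, and the two routes to
"undernutrition" agree only in prevalence, not per child. The pipeline
fits the binary outcome column by default (`undernutrition_source:
"composite"` switches to the index-derived indicator).

## Numerical choices

- Plackett solver: rationalised root, no ψ = 1 branch, Fréchet clamping;
  exactness verified to 1e−12 in tests.
- Newton fit: score tolerance 1e−6, relative log-likelihood tolerance
  1e−10, max 40 step-halvings, numeric Hessian step 1e−5 (scaled per
  coordinate).
- Degenerate inputs: both outcome levels must be present; n must exceed
  the parameter count; a constant z-score column is an error for the
  correlation matrix; an empty joint table is an error.
- JSON reports render floats rounded to 10 decimals so reruns are
  byte-identical.

## Problem sizes used in validation

Simulation-based checks run at sizes chosen to make their asymptotic
arguments sharp while keeping the suite quick: marginal-fidelity and
dependence checks at n = 10⁵ draws; parameter recovery at n = 20 000 × 100
replicates (each estimate within 3 SE of truth in ≥95%); Wald coverage for
log ψ at n = 5000 × 200 replicates (coverage in [0.91, 0.985]); oracle
equivalence against a derivative-free + quasi-Newton maximiser of the
pattern-aggregated multinomial likelihood at n = 8000 with three binary
covariates (cell probabilities to 1e−6).

## Known limitations

- Variances are inverse-information; with informative survey weights they
  understate design-based uncertainty.
- The global-ψ assumption is untested against pattern-specific dependence;
  the `psi_design` hook exists but has no accompanying inference helpers.
- The published fitted AORs from the restricted microdata are not
  reproducible here and are used only as generator truth, not as test
  targets.
- Quasi-complete separation is detected only heuristically (|β̂| > 15).
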