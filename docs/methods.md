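# Methods

This document records the statistical models, algorithms, and numerical
choices behind the `shortform` package, together with the design
decisions that are not obvious from the code and the known limitations.

## 1. Synthetic data generator (`shortform.simulate`)

Responses follow a multidimensional graded response model (GRM) in
slope–intercept form.  For item *i* with slopes **aᵢ** and strictly
decreasing intercepts *d.ᵢ₁ > … > d.ᵢ,K−1*, the cumulative boundary
probabilities are

    P(Xᵢ ≥ k+1 | θ) = logistic(aᵢ·θ + dᵢₖ),

and category probabilities are differences of adjacent boundaries.

Default instrument: 40 five-category items in four subscales of
8/12/8/12 items.  Generating parameters are simple-structure with small
cross-loadings: the dominant slope is uniform in (0.3, 2.6), off-dominant
slopes uniform in (0, 0.1).  Intercepts span roughly −7…+8 (top boundary
uniform in (1, 8), bottom in (−7, −1), interior boundaries sorted
uniforms between them).  Traits are multivariate normal with unit
variances and pairwise correlations uniform in (0.367, 0.494) (nearest
positive-definite projection applied if needed).  Two criterion scores
are linear in the traits plus noise, one negatively and one positively
oriented.  Missingness is MCAR at rate 0.04 (< 5 %).  `plant_misfit_items`
regenerates chosen items from deliberately non-GRM processes
(`category_swap`, `nonmonotone`, `shuffle`) for misfit-detection
experiments.

All randomness flows through `numpy.random.Generator` streams spawned
from a single seed (`shortform.rng`), so every artifact is reproducible.

## 2. GRM estimation (`shortform.grm`, `shortform.rotation`)

Marginal maximum likelihood by EM.  The E-step evaluates posterior
weights on a fixed grid: a tensor Gauss–Hermite grid (21/15/9 nodes per
dimension for D = 1/2/3) or a scrambled-Sobol quasi-Monte Carlo grid
(2000 nodes, standard-normal inverse transform) for D ≥ 4.  The M-step
maximizes each item's expected complete-data log-likelihood by L-BFGS-B
with intercept ordering enforced through a cumulative-difference
parametrization.  Convergence is declared on both log-likelihood change
(1e-4) and parameter change (1e-3); slopes are bounded at ±25.

Exploratory identification uses an echelon (lower-triangular) slope
constraint during estimation; the slope matrix is then obliquely rotated
by oblimin (quartimin) via the gradient-projection algorithm.  The
rotated pattern is `A @ inv(T).T` and the trait correlations are `T'T`.
`align_columns` matches estimated to reference columns greedily on
absolute correlations and resolves sign indeterminacy.  Normal-ogive
loadings use the 1.702 scaling constant.

Dimensionality is selected by refitting at each candidate D and
comparing information criteria; all four (AIC, BIC, AICc, SABIC) are
reported and BIC decides by default:

    AIC  = −2ℓ + 2q            AICc  = AIC + 2q(q+1)/(n−q−1)
    BIC  = −2ℓ + q·ln n        SABIC = −2ℓ + q·ln((n+2)/24)

## 3. S-χ² item fit and stepwise abbreviation (`shortform.itemfit`)

For each item, respondents are grouped by the summed *rest* score
(all other items).  Model-implied rest-score distributions come from the
Lord–Wingersky convolution over quadrature nodes; expected category
frequencies per rest-score group are posterior-weighted.  Sparse cells
are collapsed (rows pooled until expected counts reach 1.0, then
adjacent categories).  Degrees of freedom are
`cells − rows − q_item`, subtracting the item's parameter count because
the statistic is computed after refitting the model (Orlando–Thissen
style).  Type-I calibration of this convention was verified by
simulation: under a true 1-D model (13 items, n = 500, 200 replicates,
full refits), per-item rejection rates at α = 0.05 fall in [0.025, 0.08].

Raw p-values are adjusted by the Hochberg step-up procedure (verified
against `statsmodels` `simes-hochberg`).  Note that the Hochberg
adjustment is **not** idempotent — re-adjusting adjusted p-values changes
them (e.g. (0.25, 1.0) → (0.5, 1.0) → (1, 1)) — so the test suite checks
monotonicity properties instead.

`stepwise_abbreviate` repeatedly refits the model, tests all items, and
removes the single worst item whose adjusted p falls below α, stopping
when nothing is significant, when a subscale would be emptied
(`floor_reached`), or when estimation fails.  On clean synthetic data the
procedure correctly removes nothing; the misfit-recovery experiment
(13 clean + 27 planted items, n = 1000) recovers ≥ 80 % generator items
in 10/10 tested seeds.

## 4. Genetic-algorithm abbreviation (`shortform.ga`)

Binary keep/drop chromosomes over the item bank are evolved with
tournament selection, uniform crossover (p = 0.8), bit-flip mutation
(p = 0.1 per chromosome), elitism (5), population 100, 1000 generations
(study defaults).  Fitness is

    Cost = I·k + 1 − R²,

where k is the number of retained items and R² is the mean, over
subscales, of the variance of the full-form subscale sum scores
explained (OLS) by the retained items.  `sweep_item_cost` bisects the
item cost I to reach requested form lengths and returns the cost/R²
trade-off table.

Design note for the planted-signal sanity experiment: with the cost's
own R² definition, the full-form target *includes* any noise items, so
equal-variance noise (uniform or shuffled columns) carries irreducible
unique variance that the GA is right to keep — by exchangeable-
correlation algebra the marginal R² gain of a 4th correlated informative
item is strictly smaller than the unique variance of one noise item.
"Pure noise" is therefore implemented as zero-discrimination GRM items
with concentrated marginals (intercepts 6, 2, −2, −6; item variance
≈ 0.25); the GA then retains 4/4 informative items in all tested seeds.

## 5. Confirmatory factor analysis (`shortform.cfa`)

Simple-structure CFA on the item covariance matrix by weighted least
squares with the asymptotically distribution-free (ADF) fourth-moment
weight matrix; factor correlations are parametrized through normalized
Cholesky rows and uniquenesses through log transforms, so solutions stay
in the admissible region during optimization.  When n ≤ p(p+1)/2 the
ADF matrix is singular and the fit falls back to its diagonal (DWLS),
with a warning and an `estimator` flag on the result.

Fit indices follow the standard noncentrality formulas against an
independence baseline: χ²/df, RMSEA with a 90 % CI by inverting the
noncentral χ² CDF, SRMR on correlation-metric residuals, CFI and TLI.
Thresholds: χ²/df < 2, RMSEA < 0.05, SRMR < 0.05, CFI > 0.95,
TLI > 0.95.  Calibration check: correctly specified four-factor ordinal
data (n = 1000) passes all thresholds in 10/10 seeds.

**Limitation** — the DWLS fallback χ² is under-dispersed (χ²/df ≈ 0.6 on
correctly specified data), so RMSEA floors at 0 and CFI/TLI saturate;
no mean/variance scaling correction is applied.  Comparisons between
forms fitted with the same estimator remain meaningful, and the
correctly-specified calibration still behaves conservatively, but the
fallback χ² should not be read as a calibrated test statistic.

## 6. Psychometric battery (`shortform.psych`)

* Normalized 0–100 scoring: `(raw − min) / possible_range × 100`.
* Cronbach's α (threshold 0.60); verified against `pingouin` and a
  closed-form case (3 items, unit variance, covariance 0.5 → α = 0.75).
* Test–retest ICC(A,1) (two-way mixed, absolute agreement, single
  measurement) with McGraw–Wong confidence intervals; matches
  `pingouin.intraclass_corr` to 1e-15.  Bands: ≤ 0.4 poor-to-fair,
  ≤ 0.6 moderate, ≤ 0.8 good, else excellent.
* Floor/ceiling feasibility: < 15 % of respondents at either bound.
* Distribution screens: |skewness| ≤ 3 and kurtosis ≤ 10 (Pearson).
* Criterion validity: Pearson correlations with banding (|r| < 0.3
  poor, < 0.5 medium, else strong; non-significant at p ≥ 0.05).

## 7. Missing data (`shortform.impute`)

EM estimation of the item-score mean/covariance under multivariate
normality, then a single conditional-normal draw per missing entry,
rounded and clamped into the category range.  Observed entries are never
modified.  Items with ≥ 50 % missingness and all-missing rows are
rejected.

## 8. Pipeline (`shortform.pipeline`)

simulate → EM-impute → seeded disjoint 250/250 split → dimension
selection (calibration half) → stepwise S-χ² form and GA cost-sweep form
(calibration half) → validation battery for the full form and both
candidates (validation half, with a re-simulated 30-person retest for
ICC) → comparison by counted threshold flags, RMSEA breaking ties.
Every stage draws from child streams of one study seed; the JSON report
is byte-identical across reruns of the same config.

## 9. Problem sizes and runtimes (one CPU)

* Full study (n = 500, 40 items, default options): ≈ 4 minutes.
* D = 2 recovery (20 items, n = 1000): ≈ 6 s per seed.
* S-χ² calibration (13 items, n = 500, 200 refit replicates): ≈ 40 s.
* Stepwise misfit recovery (40 items, n = 1000): ≈ 7 s per seed.
* The whole test suite runs in well under 25 minutes.

## 10. Harness-design notes

Parameter-recovery and calibration experiments draw intercepts from
(1.0, 2.5)/(−2.5, −1.0) rather than the study generator's ±7…8 span:
with boundary intercepts near +8 the extreme categories have expected
counts below one at n = 1000, so those thresholds are statistically
unidentified and no estimator could meet tight recovery bounds.  The
study-level generator defaults are untouched; the narrower ranges make
the *harness* identifiable so that it measures estimator correctness.

End-to-end determinism is asserted by running a reduced configuration
twice and comparing report bytes, while the full-size study is run once
against the wall-clock budget — the reduced config exercises the same
code path through every stage.
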