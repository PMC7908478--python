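# Methods

This note records what the package computes, the assumptions behind each
stage, the parameters that matter, and the choices made where the design
was genuinely open.

## 1. Synthetic study generator

The generator emulates a tract-level demographic table joined to a
small-area-estimated health prevalence, with every property the pipeline
must survive, and carries its ground truth for recovery testing.

**Latent structure.** `generate_truth(k, p_core, seed)` draws a
simple-structure pattern matrix: variables assigned to factors round-robin,
primary loadings uniform on [0.55, 0.8], cross-loadings uniform on
[−0.1, 0.1], rows rescaled so no communality exceeds 0.9. Factor
correlations are uniform on [−0.4, 0.4] (resampled until
positive-definite), matching the magnitude oblique demographic factors
show in practice. Uniquenesses are set to 1 − communality, so each core
column `F·λᵢ + eᵢ` has unit variance before its marginal map.

**Marginal skew maps.** Applied round-robin over the core columns:
`exp(z/2)` (dollar-amount-like right tails), `(z+5)²` (a monotone shifted
square; a raw square would be non-invertible and no transform could undo
it), `logistic(z − 1.5)` (right-skewed small shares — demographic
proportions are typically small with a tail; a centered logistic map would
be symmetric and need no transform at all), and identity. Each map has
exactly one inverse in the transform menu, which is what makes the
"planted map inverted" property testable.

**Planted artifacts.** Complement columns `1 − x` of proportion cores
(declared in the catalog); a near-constant column (CV ≈ 0.002); one
stratum group — a proportion core withheld from the table and replaced by
Dirichlet-weighted subgroup columns that sum to it exactly; missing cells
completely at random at rate 0.0016 (the observed missingness scale of
such tables), never leaving a row fully missing.

**Outcome.** `prevalence = expit(β₀ + Fβ + Cγ + u_state + u_county + ε)`
with independent normal intercepts and noise. Defaults: β₀ = logit(0.12)
(a realistic national poor-mental-health baseline), factor coefficients
(−0.5, 0.1, 0.3, 0.15, 0.25) on the logit scale per factor SD, state /
county / residual SDs 0.2 / 0.1 / 0.15. Confounders (age, sex ratio,
minority share, poverty) are linear images of the factors plus noise at
R² = 0.5 by default, so they genuinely confound the factor–outcome
relationship the way covariates baked into a small-area estimate would;
`confounder_loadings` lets a scenario concentrate them on one factor.

**What the generator does not emulate:** spatial autocorrelation between
neighboring tracts, survey margins of error, geographic imbalance (equal
tracts per county by default), and real FIPS codes. Passing tests
therefore demonstrate correctness of the pipeline's computations under a
faithful factor model, not robustness to spatially structured noise.

## 2. Feature selection

Order: redundancy → low-CV filter → strata combination. Redundancy is
catalog-declared rather than auto-detected by correlation: the motivating
examples (female share = 1 − male share) are definitional, and silent
auto-detection would change the variable set unaccountably. The CV filter
removes columns with sd/mean < 0.06, computed on raw values with the
sample (n−1) standard deviation, ignoring missing entries; columns with
non-positive mean have no defined CV and are always retained (and logged).
Strata combine by `sum` for proportion subgroups and by `weighted_mean`
with bin-midpoint weights for ordered bins; missingness in any subgroup
propagates. The three logs concatenated account exactly for the change in
column count.

## 3. Transformation and imputation

Candidate families, in preference order: identity, log(x + shift) with
shift = max(0, ε − min), √x (non-negative columns), logit (columns in
[0, 1], edges clipped inward by ε), Yeo–Johnson with maximum-likelihood λ.
ε is half the smallest positive observed value (or distance from 1). The
family minimizing |sample skewness| wins; the earliest family within 0.1
of that minimum is preferred. The 0.1 tolerance is about three sampling
standard deviations of the skewness estimate at n ≈ 5000 and below any
practically meaningful asymmetry — without it the flexible Yeo–Johnson
family would displace the structurally correct simpler transform on pure
sampling noise. Standardization (mean 0, sd 1 over non-missing cells)
happens after transformation, as the k-NN metric requires.

Imputation: for each missing cell, the inverse-distance-weighted
(w = 1/(d + 10⁻⁸)) average of the 10 nearest rows, with Euclidean distance
over shared non-missing columns rescaled by √(p / p_shared) so sparser
overlaps are not rewarded. Observed cells are never modified; a neighbor
set with no observed donor falls back to the column mean with a warning.
Single (not multiple) imputation: at 0.16% missingness the imputation
uncertainty is negligible for the downstream covariance estimates.

## 4. Factor model

**Extraction.** Uniquenesses minimize the least-squares residual of
R − diag(ψ) against its rank-k eigen-approximation (L-BFGS-B with the
exact envelope gradient −2·diag(residual); ψ bounded in [0.005, 1]). At
the optimum the diagonal residuals vanish, so this attains the classical
minimum-residual criterion on the off-diagonals; communalities above 0.995
(Heywood cases) are clamped with a warning (configurable to abort).

**Rotation.** Direct oblimin with γ = 0 (quartimin) via oblique gradient
projection, the common default of the EFA software family; convergence at
projected-gradient norm 10⁻⁶. Identifiability conventions: each factor's
largest-|loading| entry is positive, and factors are ordered by descending
variance explained (diag(ΦΛᵀΛ)/p, the oblique analogue of sum of squared
loadings).

**Diagnostics.** Kaiser count applies the ≥ 1 rule to the eigenvalues of
the *observed* correlation matrix. The scree elbow is the count of
eigenvalues preceding the point of maximum second difference of the
**log** eigenvalues: the elbow of a scree curve is where the relative
decay collapses into the flat noise tail, and on the raw scale the widely
spaced leading eigenvalues of a strong oblique structure mask that break.
Fit statistics: rms_residual is the RMS of off-diagonal residuals of
R − ΛΦΛᵀ; offdiag_fit = 1 − Σresid²/Σr² over off-diagonals.

**Scores.** Thurstone regression scores W = R⁻¹ΛΦ on the standardized
data (ridge 10⁻⁸ if R is singular). **Bootstrap.** Rows resampled with
replacement; each refit is aligned to the full-sample reference by
Hungarian assignment on |Tucker congruence| with sign flips — without
alignment, factor order/sign indeterminacy would make the SEs meaningless.
Refits are warm-started at the reference uniquenesses. Resamples that fail
to converge are dropped; more than 5% dropped is an error.

**Naming.** Factor labels are left to the user; the analysis scripts
report the top-loading variables per factor instead, since any one-word
name under-describes a latent dimension.

## 5. Association

**Splines.** Cubic smoothing splines of prevalence on score, one per
state, penalty chosen per state by generalized cross-validation
(`scipy.interpolate.make_smoothing_spline`); duplicate abscissae are
averaged with multiplicity weights before fitting since the routine
requires strictly increasing knots. R² = 1 − SSres/SStot; states with
fewer than 20 tracts (configurable), constant outcome, or fewer than 5
distinct scores are excluded and logged. Summaries are the median and
[25th, 75th] percentiles of R² across states.

**Mixed models.** `prevalence ~ fixed + (1|state) + (1|county:state)`,
identity link on the proportion (logit-link modeling is possible by
transforming the outcome upstream but is not the default), fitted by
maximum likelihood — not REML — so variance totals are comparable across
models with different fixed effects, which the R² differences require.
The county intercept is a variance component nested inside the state
grouping, since county codes are only unique within a state. V in the R²
formula is the **total** unexplained variance (state + county + residual):
this makes R² respond to fixed effects that act at any level of the
hierarchy; a residual-only reading would credit a state-level covariate
with nothing. Negative variance components from singular fits are clamped
to zero with a warning; tiny negative f² increments (ML numerical noise)
are floored at zero.

**Effect sizes.** f² = (R²_with − R²_without)/(1 − R²_with) labeled by the
conventional ≥ 0.02/0.15/0.35 rule as small/medium/large. The published
decomposition table bundled in `association.PUBLISHED_DECOMPOSITION`
carries its printed R² columns as inputs; unique variance re-derives from
them exactly at printed precision, while f² re-derives only to ~5×10⁻⁴
because the printed f² were computed from unrounded R² — comparisons
against it should use 10⁻³, the precision the 4-decimal inputs support.

## 6. Problem sizes and determinism

Default study conditions: 5 factors, 39 core variables, 5000 tracts, 20
states × 4 counties, 0.16% missingness — large enough that loading
congruence to truth exceeds 0.99 and score–truth correlations 0.93, small
enough that the full pipeline (including a 200-resample bootstrap used for
stability metrics; the analysis scripts use the full 2000) runs in well
under a minute. All randomness flows through explicit integer seeds;
identical config + inputs + seed reproduce artifacts byte-for-byte.

## 7. Known limitations

- Oblimin is the only rotation implemented (γ = 0); no promax/varimax.
- The transform menu is a fixed heuristic; a column whose skew no family
  can remove keeps its best available transform silently.
- k-NN imputation at high missingness (> a few %) would distort the
  correlation matrix toward the mean; the pipeline is designed for the
  sub-1% regime.
- The mixed models treat the prevalence as homoskedastic on the identity
  scale; small-area-estimated outcomes in truth have tract-varying
  precision that is not modeled.
- No spatial correlation structure anywhere: state/county intercepts are
  the only geographic dependence.
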