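# Methods

## The biometrical model

The likelihood unit is the twin pair. For a univariate phenotype (an
acceleration score), the pair vector `(y1, y2)` is modeled multivariate
normal with mean `μ` (equal across twin order and zygosity) and covariance

    Var(y)        = a² + c² + e²               (ACE)   or  a² + d² + e²  (ADE)
    Cov(y1, y2)   = k_A a² + c²                         or  k_A a² + k_D d²

with `k_A = 1` (MZ) / `0.5` (DZ) and `k_D = 1` / `0.25`. The model assumes
random mating, equal shared environments for MZ and DZ pairs, and no
gene-environment correlation; C (shared environment) and D (dominance) are
not jointly identified with twins reared together, so the ACE-vs-ADE choice
follows the twin correlations: ADE iff `r_MZ > 2 r_DZ`, ties to ACE.

Paths are parameterized unconstrained (sign-indeterminate) with latent factor
variances fixed to 1; variance components are reported as squared paths,
which keeps the optimization smooth and automatically enforces component
non-negativity. Minimization is quasi-Newton (L-BFGS-B, gradient tolerance
1e-8) from a Falconer-moment start plus jittered restarts (5 by default,
seeded); the convergence flag requires optimizer success and agreement of at
least two starts within 1e-4 in -2LL. A non-positive-definite implied
covariance returns a large finite penalty instead of raising, so line
searches can back away. For non-moderated models the -2LL is evaluated from
per-group sufficient statistics (exactly equal to the per-pair sum);
moderated models evaluate the covariance per pair at the pair's age
(definition variable), vectorized through the analytic 2x2 inverse.

Phenotypes with pooled variance below 1e-3 (pace-of-aging scores, whose
components are of order 1e-3) are internally rescaled to unit order and the
estimates and -2LL back-transformed; this is purely a conditioning device.

## Bivariate correlated-factors model

Across the two measurement occasions the pair vector is
`(twin1-t1, twin1-t2, twin2-t1, twin2-t2)`; factor loadings are fixed to 1,
factor standard deviations are free per occasion, and same-kind factors
correlate across occasions (`r_A`, `r_C`/`r_D`, `r_E`). Cross-twin blocks
weight the genetic terms by the zygosity coefficients and drop E. The
equality-over-time test refits with `σ_t1 = σ_t2` for the named components
and compares by chi-square difference (df = number of constraints).

## Age moderation

Each moderated path is linear in age, `x(age) = x0 + x1·age` with age
**uncentered** (years), so published component-by-age grids map directly
onto path evaluations; the means model adds independent linear and quadratic
age terms. The full ACE/ADE moderation model has 9 free parameters
(3 baselines, 3 slopes, `μ0`, `β_age`, `β_age²`). `moderation_ladder`
backward-prunes slopes: a drop is committed when it is not significantly
worse by chi-square difference (α = 0.05) and lowers the AIC. Moderated
components at a given age are `x(age)²`; `linear_path_from_endpoints`
calibrates `(x0, x1)` through the square roots of two endpoint components,
which is how published endpoint grids are converted into generating or
comparison parameters.

With all three slopes free, A- and C-slope contributions are only weakly
separated (they differ only through the DZ contrast), so the full
9-parameter likelihood can be multi-modal; the multi-start policy reports
the best optimum and flags disagreement via the convergence flag. The
single-slope models used for pruning decisions are well identified.

## Model selection

The nested ladder (ACE, AE, CE, E; or ADE, AE, E) tests each reduction
against the full model by chi-square difference; among the full model and
all reductions not significantly worse (α = 0.05), the lowest AIC wins, with
AIC ties below 1e-6 resolved toward fewer parameters. Chi-square difference
tests use the standard (non-mixture) reference distribution, the convention
of the reported analyses this pipeline mirrors; the boundary-mixture
alternative applies to the *power* module (below).

## Confidence intervals

90% intervals are profile-likelihood based: the set of fixed parameter
values whose profiled -2LL stays within the chi-square(1) 0.90 quantile of
the minimum, with all other parameters re-optimized; bounds are located by
bracketed root-finding. Path and factor-SD parameters are profiled on the
non-negative half-line (they are sign-indeterminate), so a boundary estimate
yields an exact lower limit of 0, and the interval is also reported on the
squared (component) scale. Whether published twin-model CIs are
likelihood-based or delta-method is often unstated; these are
likelihood-based and labeled as such.

## Assumption checks

The twin-model preconditions — equal means and variances across co-twins and
zygosity groups — are tested by comparing the saturated per-group bivariate
normal (closed-form MLE at the sample moments) against constrained variants
(means block, df 3; variances block, df 3; omnibus, df 6) with within-pair
correlations left free per zygosity.

## Acceleration scores

Acceleration is the per-occasion OLS residual of the clock value on the
covariate set, cohorts pooled within occasion (a per-cohort option exists).
Defaults per clock: chronological age, sex, and the cell-composition
principal component for all clocks except DunedinPACE (a rate, not an
accumulated age, so age is not partialled out of it); the smoking-probe beta
(cg05575921) additionally for Horvath, PedBE, and DunedinPACE but not
GrimAge (smoking is part of its training signal). Sex is coded 0/1; cell
composition enters as one principal-component score computed upstream.
Missing values are handled by listwise deletion within occasion, with counts
logged. Residual means are zero per occasion by construction; per-cohort
means are free to deviate. DunedinPACE adjustment is implemented as
residualization (mean-zero scores), consistent with near-zero reported
descriptive means for adjusted pace scores.

## Power analysis

For a drop-one-component test, the implied MZ/DZ population covariances are
built under the true model and the reduced model is fitted to those moments
weighted by pair counts; the minimized ML discrepancy

    F = Σ_g n_g [ ln|Σ(θ)| − ln|Σ_0| + tr(Σ(θ)⁻¹ Σ_0) − p ]

is the non-centrality parameter, exactly linear in total pair count at fixed
MZ:DZ ratio. Because a variance component sits on the boundary of its space
under the null, the LRT's null reference is the 50:50 mixture of χ²(0) and
χ²(1); the default critical value is therefore the χ²(1) quantile at
1 − 2α (the convention of the standard twin-power calculators, and the rule
that reproduces published twin-power values), with the plain central χ²(1)
rule available via `boundary_mixture=False`. Monte-Carlo cross-validation
simulates pair vectors from the true covariances, fits full and reduced
models, and applies the same critical value; under a null scenario the
half-mass atom of the LRT at zero makes the empirical size come out at α,
which the test suite verifies. The two-group (binary-moderator) variant
constrains a named component's path equal across two groups fitted jointly,
giving power for component differences such as between the youngest and
oldest age groups.

## Synthetic cohort generator

The generator emulates a four-cohort same-sex twin panel measured twice
~2.5 years apart: cohort mean ages 9.5 / 15.5 / 21.5 / 27.5 at occasion 1
(within-cohort age SDs 0.33 / 0.31 / 0.37 / 0.70), MZ/DZ pair splits
82/81, 87/99, 42/34, 52/11 (263 MZ + 225 DZ = 488 pairs, 976 individuals).
Factor scores are constructed exactly: DZ genetic scores as
`√k·shared + √(1−k)·unique` (k = 0.5 additive, 0.25 dominance), shared
environment identical within pair, unique environment independent, and
cross-occasion correlation via the Cholesky factor of `[[1, r], [r, 1]]`,
so all within-pair and cross-time correlations hold by construction rather
than approximately. Ages are Normal(cohort mean, SD) truncated at ±3 SD and
shared by co-twins (within-pair age differences are zero — a declared
simplification). Sex is Bernoulli(0.5) shared within pair; the cell-type PC
is standard normal; the smoking-probe beta is a Beta(8, 2) draw bounded in
[0, 1]; covariate effect sizes default to zero. By default the generator
emits the acceleration-scale score itself; `emit_epigenetic_age=True` adds
chronological age back so the residualization stage can be exercised end to
end.

What the generator does **not** emulate: CpG-level beta matrices, batch or
plate structure, non-normal score distributions, within-pair age
differences, cohort effects distinct from age effects, and attrition
patterns. Passing tests therefore demonstrate correctness of the estimators
and procedures under the stated data-generating model, not robustness to
those real-data complications.

## Problem sizes and numerical choices in the test suite

Statistical acceptance checks use: 2000+2000 pairs per dataset for
univariate recovery (10 replicates; single-draw share estimates have
sampling SD ≈ 0.04 at this size, so recovery/bias is assessed on the
replicate mean), 1000+1000 pairs for bivariate recovery (6 replicates),
50 replicates for moderation-slope CI coverage and for ladder selection
consistency, 1000 replicates for assumption-check size and 300 for
equality-over-time size. Monte-Carlo power uses 1000 replicates with 2
optimizer starts per fit. Percent shares round half away from zero to
integers for report parity with published tables.

## Known limitations

* Pooling the two occasions into one univariate sample deliberately ignores
  within-person clustering (mirroring the analysis design this package
  reproduces); the first-occasion-only refit is available as a sensitivity
  toggle.
* No sex-limitation, extended-pedigree, or joint ACDE models; no
  continuous-moderator analytic power (the two-group binary-moderator
  approximation stands in for it).
* The moderation model is linear in age; genuinely non-linear moderation
  would be absorbed into the means model's quadratic term or missed.
* DNAm preprocessing, clock computation from CpG matrices, cell-type
  deconvolution, and zygosity determination are all upstream of this
  package: clock values, the cell PC, and the smoking-probe beta enter as
  given columns.
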