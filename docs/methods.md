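# Methods

## Scope and estimands

The package measures output-oriented productive efficiency of
decision-making units (DMUs) relative to an empirical frontier, decomposes
it into pure technical and scale components, corrects the well-known
optimism of DEA scores by a smoothed homogeneous bootstrap, and explains
the corrected scores with environmental covariates through a
truncated-normal regression with parametric-bootstrap inference.  Scores
are computed and bootstrapped on the Farrell scale (λ ≥ 1, the maximal
proportional output expansion) and reported on the Shephard scale (1/λ in
(0, 1]); the decomposition `TE = PTE × SE` is definitional and exact.

## Envelopment programs and numerics

Each score is the optimum of a small linear program.  All units that share
one reference technology are stacked into a single block-separable sparse
LP (the blocks do not interact, so the joint optimum solves each unit
exactly) and handed to HiGHS; evaluation sets larger than 32 units are
chunked because simplex time grows superlinearly in the stacked size.
Input and output columns are normalised by their column maximum before
solving — the Farrell score is invariant to per-dimension rescaling, and
this keeps hospital variables with wildly different natural units (10,000
RMB expenditures next to bed counts) well conditioned; it is also what
makes the units-invariance property hold to ~1e-15 rather than solver
tolerance.  Scores within 1e-8 of 1 are snapped to exactly 1 for band and
returns-to-scale reporting, and the theoretical nesting
`λ_VRS ≤ λ_NIRS ≤ λ_CRS` is enforced on the solver output (violations are
round-off), which makes `PTE ≥ TE` and `SE ∈ (0, 1]` exact.

Returns-to-scale classification uses the NIRS rule with tolerance 1e-6: a
unit is CRS when its CRS and VRS scores agree; otherwise IRS when the NIRS
score equals the CRS score (the CRS projection scales the hull down, which
NIRS admits — the unit is below its most productive scale size) and DRS
when it equals the VRS score instead.

## Smoothed homogeneous bootstrap

One replication resamples the estimated scores with replacement, adds
Gaussian kernel noise with bandwidth `h`, reflects draws below 1 about the
frontier, shrinks deviations by `1/sqrt(1 + h²/var(λ̂))` to undo the
variance inflation of the smoothing (re-reflecting any stragglers),
deflates every unit's outputs by the drawn inefficiency relative to its
estimated one — inputs are never perturbed, matching the output
orientation — and re-solves the DEA of every original unit against the
pseudo reference set.  The bandwidth is the robust Silverman rule
`0.9 · min(sd, IQR/1.349) · (2n)^(-1/5)` on the reflected 2n-sample; when
the interquartile range is zero but the spread is not, the standard
deviation is used alone, and when all scores coincide the bootstrap
degrades gracefully to naive resampling (`h = 0`, flagged).  Bias-corrected
Farrell scores `2λ̂ − mean_b(λ*)` that fall below 1 are clamped to 1 and
flagged; confidence intervals are basic-bootstrap percentile intervals of
`λ* − λ̂`.  The default B = 2000 replications matches common practice for
publication-grade runs; tests use 100–200 for speed.

Bias-corrected scale efficiency is reported as the ratio of bias-corrected
TE to bias-corrected PTE; it is not separately bootstrapped, and the ratio
may exceed 1 for individual units after correction (reported as-is in the
per-unit table, capped at 1 only for band summaries).

## Truncated regression and the double bootstrap

The second stage is maximum likelihood on `(β, log σ)` with analytic
gradients (L-BFGS-B from a least-squares start, BFGS fallback), with the
truncation-mass terms computed in log space so that deep-tail likelihood
and hazard ratios do not underflow.  The Wald statistic for joint covariate
nullity comes from the observed information.  The double bootstrap follows
the standard two-loop design: L1 regression-based parametric bootstrap
loops estimate and remove each score's frontier bias, the regression is
refitted on the bias-corrected scores (scores clamped to the frontier are
excluded, with a reported count), and L2 loops around that refit give
percentile confidence intervals.  A single-loop variant on the raw scores
is exposed as well.  Defaults L1 = 100, L2 = 2000.  Both response
conventions are available: `farrell_ge1` (native scale of the algorithm,
left truncation at 1; positive coefficients mean more inefficiency) and
`shephard01` (scores in (0, 1), two-sided truncation, signs align with
reporting conventions that regress TE directly).  Covariates named
population, GDP per capita, financial subsidy and average staff income
enter in logs by default, mirroring standard practice for scale-like
covariates; the transform list is configurable.

## Synthetic generator

The generator mirrors the two-stage estimating model so that ground truth
is recoverable: inputs and covariates are drawn from per-group normal
scales floored at 1e-6 of their mean (all quantities are physically
nonnegative); the frontier is Cobb–Douglas `c_m Π x_k^α_k` with
`α_k ≥ 0, Σα_k ≤ 1`; Farrell inefficiency is `δ = z̃β + ε` with ε normal,
left-truncated so δ ≥ 1, where z̃ are covariates standardised by their
configured scales; observed outputs are frontier outputs divided by δ.
True δ is stored on the panel and never read by estimators.

Three ready-made configurations:

* `default_table2_config` — the survey-shaped panel: 33 district and 84
  county hospitals, five inputs and four outputs at published per-group
  descriptive scales, six covariates (population, GDP per capita, financial
  subsidy, professional share, trained workers, staff income).  Output
  multipliers are calibrated so per-group mean *frontier* outputs match the
  published output means (a deterministic Monte-Carlo constant with a fixed
  internal seed).  Inefficiency effects on the standardised scale:
  intercept 1.5, subsidy −0.05, professional share −0.15, trained workers
  −0.15, zero for the rest, σ = 0.15 — plausible magnitudes for the
  pattern that workforce quality and funding improve efficiency.
* `recovery_benchmark_config` — the Monte-Carlo design for second-stage
  recovery: 100 units, two inputs, one output, constant-returns frontier,
  three covariates with effects +0.4, −0.3 and 0.0, σ = 0.15.  Low
  input-output dimension keeps the frontier bias small at n = 100, which is
  what makes coefficient recovery a sharp test of the double bootstrap.
* `coverage_benchmark_config` — the interval-calibration design: 50 units,
  two inputs, one output, decreasing-returns frontier, *homogeneous*
  (intercept-only) boundary-peaked inefficiency with σ = 0.2, because the
  homogeneous bootstrap's validity argument assumes inefficiency identically
  distributed across units.

What the generator deliberately does not emulate: survey non-response,
measurement error, spatial structure, case-mix or quality differences.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to those real-data features.

## Pipeline and reproducibility

The pipeline analyses each group against its own frontier by default
(pooled analysis behind a flag), bootstraps TE and PTE separately, compares
groups with the pooled-variance Student's t-test, and writes a bundle of
CSV tables plus one combined JSON report and a manifest.  All randomness
descends from one root seed via deterministic seed-sequence spawning, so a
fixed configuration reproduces the bundle byte for byte; wall-clock timings
go to a separate `timings.log` outside the reproducible set.

Variable screening (optional) follows the common funnel: average-linkage
hierarchical clustering of candidates on `1 − |r|` distance, dropping one
member of each pair with `|r| > 0.9` (the member whose variation the output
set explains less — ties broken lexicographically so the screen is
column-order invariant), then retaining inputs with `R² > 0.5` against the
selected outputs.  Both thresholds are configurable; the clustering is
descriptive and the drops are annotated with the rule that fired.

## Known limitations

* **Per-unit bootstrap interval calibration.**  On known-truth panels
  (n = 50, B = 200) nominal 95% intervals cover the true Farrell score in
  about 70% of unit–panel pairs under the homogeneous design, and far less
  when inefficiency is strongly covariate-driven.  Diagnostics against a
  ground-truth Monte Carlo of the estimator's sampling distribution show
  the bootstrap reproduces the *aggregate* error law well; the shortfall is
  that one homogeneous error distribution is assigned to every unit, while
  actual errors are heterogeneous (frontier-adjacent units have almost
  none), so misses are one-sided.  This is the documented small-sample
  behaviour of these intervals; treat per-unit intervals as indicative and
  prefer group-level summaries.
* **Intercept of the second stage.**  In recovery experiments the covariate
  effects are estimated essentially unbiasedly with ≥ 90% CI coverage, but
  the intercept absorbs the residual error of the frontier-bias correction
  and its interval undercovers mildly (~82% at n = 100); interpret the
  intercept as a level parameter, not an effect.
* **Dimensionality.**  With five inputs and four outputs, samples of 33–117
  units leave many units on or near the empirical frontier (the usual DEA
  dimensionality curse); raw and corrected scores are then compressed
  upward and second-stage information is thin.  The survey-shaped default
  reproduces this property faithfully — it is a feature of the design, not
  of the estimator.
* No slack-based or super-efficiency measures, no input orientation, no
  Malmquist indices, no heterogeneous or subsampling bootstrap.
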