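# Methods

## Models and routes

Each count dataset has a response `y` (non-negative integers) and one
explanatory variable, either categorical (`oneway`) or continuous
(`regression`). Three analysis routes are fitted to every dataset:

* **sqrt_lm** — OLS of √(y + c) on the design matrix. Offset presets
  c = 0 (default), 0.5 and 0.375 follow the classical
  variance-stabilising recommendations for Poisson counts; any
  non-negative c is accepted.
* **log_lm** — OLS of log(y + c) with default c = 1 (the usual guard
  against log 0) and base e; base 10 is a configuration option.
* **glm** — log-link GLM with Poisson or negative-binomial errors,
  fitted by IRLS: working response z = η + (y − μ)/μ, weights
  w = μ (Poisson) or μ/(1 + μ/θ) (NB), initialised at μ⁽⁰⁾ = y + 0.5,
  converged when max|Δβ| < 1e-8, capped at 100 iterations
  (non-convergence raises). The NB variance is μ + μ²/θ, so
  θ → ∞ recovers Poisson; with θ fixed at 1e8 the NB fit agrees with
  the Poisson fit to well under 1e-6, which the tests assert.

Designs use treatment coding with the alphabetically first level as
reference, so a one-way group mean on the link/transformed scale is
always intercept + factor coefficient.

When θ is not supplied it is estimated by profile likelihood:
alternate IRLS for β given θ with a bounded one-dimensional
maximisation of the NB log-likelihood in log θ over [−7, 12]
(SciPy's bounded Brent minimiser, xatol 1e-10), stopping when the
log-likelihood improves by less than 1e-8. Bounded Brent was chosen
over plain golden-section as the readily available, strictly more
efficient bracketing method; the optimum is identical to the stated
tolerance.

## Tests of the predictor term

* LM routes: overall F-test of the full model against intercept-only.
  A saturated or perfect fit makes the F statistic degenerate; the
  convention is p = 0 when the predictor absorbs all variation with no
  residual left and p = 1 when the response is constant.
* GLM route: likelihood-ratio (analysis-of-deviance) χ² test against
  the intercept-only fit, with θ held at the full-model estimate for
  both fits so the test compares mean structures, not dispersions.

With a single predictor these are the canonical choices; nothing in
the package depends on ANOVA-table ordering.

## Family selection

The visual residual-plot judgement that usually drives the
Poisson-vs-NB choice is replaced by a reproducible rule: fit Poisson,
compute the Pearson dispersion χ²/(n − p), and switch to NB when it
exceeds a threshold (default 1.5, configurable; ∞ disables NB). The
dispersion statistic is always reported. In Monte-Carlo loops a
replicate whose NB θ-estimation fails falls back to the Poisson fit
and is flagged, keeping rejection-rate denominators honest.

## Back-transformation conventions

These conventions are the package's subject matter, so they are fixed
and logged per run rather than silently defaulted:

* **sqrt route** — square the transformed-scale quantity and reapply
  its original sign (a squared negative slope stays negative). The
  forward offset c is *not* subtracted after squaring; the provenance
  string records the offset so the choice is visible. This matters
  whenever c > 0 and is deliberate: the convention under study squares,
  full stop.
* **log route** — base^m − 1 for every quantity m (group mean sums,
  intercept, slope), base e by default. Note the asymmetry: the
  forward transform adds c = 1 *inside* the log, while the inverse
  subtracts 1 *outside* the exponential, so this is a geometric-mean
  style estimate, not an algebraic inverse. The exact inverse
  (base^m − c) is available as `invert_transform` for sensitivity
  checks, but the comparison pipeline uses base^m − 1 as stated.
* **glm route** — group means e^(β₀+β_level) (exponentiated intercept
  times exponentiated factor coefficient, the only reading that yields
  count-scale means under a log link); regression intercept e^β₀ and
  slope e^β₁ − 1, the proportional change per covariate unit minus one.

`OriginalScaleEstimates.provenance` names the formula applied so
alternative conventions (e.g. base-10, offset-corrected) can be
compared side by side.

## Comparison surfaces

* **Decisions** — reject/retain at a fixed α (default 0.05);
  `decisions_agree` is true when all three routes decide alike.
* **% difference** — 100·(LM − GLM)/GLM per coefficient; undefined
  (reported as missing, never ±∞) when the GLM estimate is zero. On
  all-positive one-way data the concave transforms guarantee this is
  ≤ 0 for every group mean (Jensen's inequality), which the test suite
  asserts on randomly drawn datasets.
* **Diagnostics** — residual-vs-fit per route: raw residuals on the
  transformed scale for the LM routes, deviance residuals against
  link-scale fitted values for the GLM (the standard GLM diagnostic).
  The smooth is lowess with tricube weights and span 0.75
  (configurable). "Fan shape" is operationalised as the Spearman rank
  correlation of |residual| with fitted value; a suite-level count
  flags datasets where the sqrt route's fan index exceeds both other
  routes' by a margin (default 0.1). Degenerate clouds (constant
  fitted values or constant |residual|) have no fan trend and get
  index 0; n < 3 yields NaN, and n < 4 skips smoothing.

## Synthetic data

The generator emulates the structure of the textbook case datasets the
comparison was designed around: one-way layouts with 2+ groups of
Poisson (optionally NB-overdispersed) counts, and log-linear
regressions with a deterministic, evenly spaced covariate — mirroring
year-indexed count series and removing design randomness from recovery
studies. Zeros occur naturally at small means; there is no
zero-inflation mechanism. Defaults used throughout the bundled studies
(chosen once as realistic for small ecological datasets, since the
case studies' own sample sizes are not a published fact): 30
observations per group, group means in the low single digits to low
tens.

What the generator does *not* emulate: multi-factor designs, unequal
group sizes, offsets/exposure, serial dependence, or excess zeros
beyond the error model. Passing tests therefore demonstrate correct
behaviour under a correctly specified Poisson/NB world, not robustness
to the messier features of field data.

## Monte-Carlo studies

Replicate r of a study with master seed s uses derived seed
(s + r) mod 2³¹; studies are exactly reproducible and could be
parallelised without shared state. Replicate failures are counted,
and more than 5% aborts the study.

* **Type-I error** — null datasets (common mean / zero slope), all
  three routes, rejection rate per route with Monte-Carlo standard
  error √(r(1−r)/n_reps). The bundled configuration is a Poisson
  one-way null with mean 5 and 30 per group, 2000 replicates at
  α = 0.05; a second check at mean 20, n = 50 confirms the GLM's LR
  test approaches the nominal level as the asymptotics improve.
* **Recovery** — non-null scenarios with known truth. Count-scale
  truth is the generating group means (one-way) or e^β₀ and e^β₁ − 1
  (regression); bias and RMSE are reported per route, plus for the GLM
  route the mean link-scale coefficients and 95% Wald coverage of the
  generating β. The bundled regression scenario uses β = (1.0, 0.3)
  with n = 200 over a covariate range of (0, 2) — means between ~2.7
  and ~5, comfortably in the small-count regime where transformation
  bias is visible — and 500 replicates.

Problem sizes throughout (2000 type-I replicates, 500 recovery
replicates, oracle checks at n ≤ 30) are the package's own choices:
large enough that binomial Monte-Carlo error is a fraction of the
effect being measured, small enough to keep the full study
interactive.

## Numerical and degenerate-input choices

* OLS solved by `numpy.linalg.lstsq`; rank-deficient designs raise.
* All-zero responses raise for the GLM (the log-link mean is
  unidentifiable at −∞).
* Pearson dispersion raises when any fitted mean is zero.
* IRLS standard errors come from (XᵀWX)⁻¹ at convergence.
* Output tables are written with ≥ 10 significant digits so
  deterministic runs are byte-comparable.

## Known limitations

* Single-predictor models only; no offsets, mixed effects, or
  quasi-likelihood.
* The NB LR test conditions on the estimated θ rather than profiling
  it per hypothesis; with a single predictor the difference is
  negligible but it is a simplification.
* Back-transformed estimates carry no uncertainty (no delta-method or
  smearing corrections) — deliberately, since the point estimates'
  conventions are the object of study.
* The family-selection threshold (1.5) is a pragmatic rule of thumb,
  not an inferential test; borderline dispersion near the threshold
  flips the family discontinuously.
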