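# Methods

## Model and procedure

The pipeline has three statistical stages.

**1. Effect-measure harmonisation.** All downstream formulas are
defined on the risk-ratio scale, so every input estimate is converted
first. Odds ratios use `RR = OR/(1 − p0 + p0·OR)` with `p0` the
baseline (reference-group) outcome risk; `p0` is a required input
wherever an OR must be converted — there is no silent default, because
the conversion is sensitive to it (OR 1.58 is RR 1.48 at p0 = 0.12 but
only RR 1.22 at p0 = 0.5). Hazard ratios for rare outcomes pass
through; for common outcomes (outcome proportion above 15%) the
approximation `RR = (1 − 0.5^√HR)/(1 − 0.5^√(1/HR))` is used, which is
reciprocal-symmetric and shrinks the HR toward the null. Correlations
enter through the standardized-mean-difference chain
`d = 2r/√(1 − r²)`, `log OR = π·d/√3` (the logistic-scale conversion),
which maps r = 0.28 to OR 2.88; the resulting OR still needs a `p0` to
become an RR. Conversions are applied to the point estimate and both
CI limits; no CI propagation is attempted for the r → OR step, which
is used for point scenarios only. The standard error of a log effect
is recovered from CI limits as `(ln U − ln L)/(2z)` with the z-quantile
at full precision (1.959964 at 95%), not 1.96, matching standard
meta-analysis tooling.

**2. REML random-effects meta-analysis.** Study-level log RRs follow
the normal-normal model `y_i ~ N(θ, se_i² + τ²)`. τ² maximises the
restricted log-likelihood

    −2·ll_R(τ²) = Σ ln(se_i² + τ²) + ln Σ w_i + Σ w_i (y_i − θ̂)²,
    w_i = 1/(se_i² + τ²),

by bounded derivative-free scalar minimisation (tolerance 1e−10),
which is robust at the τ² = 0 boundary; the boundary itself is checked
explicitly and preferred when at least as likely. The search bracket
is `[0, 10·(max se² + var y)]`: including the raw variance of the
estimates keeps the optimum inside the bracket even when sampling
variances are tiny relative to the heterogeneity. The pooled effect is
the inverse-variance weighted mean at the estimated τ², with a Wald CI
on the log scale (no Hartung-Knapp adjustment, matching the default of
the standard R tooling this estimator was cross-checked against).
Cochran's Q uses fixed-effect weights and I² = max(0, (Q − (k−1))/Q).
A single-study "meta-analysis" returns the study itself with τ² = 0
and a warning rather than an error, so batch runs over sparse
quantiles never crash. Each exposure quantile is pooled independently
against the declared reference quantile (default Q1); correlation
between quantile contrasts within a study is ignored, as is standard
when only published per-quantile estimates are available.

**3. Sensitivity analysis.** E-values, the joint bounding factor B,
proportion explained `100·(B − 1)/(RR − 1)` (excess-relative-risk
scale, capped at 100), the closed-form complementary strength
`x = t·(a − 1)/(a − t)` solving `B(a, x) = t`, and contour emission.
Conventions, each chosen where the field's usage is loose:

- *Orientation.* Protective estimates are reciprocated before any
  formula; all results are reported on the ≥ 1 side. Scenario
  strengths must be pre-oriented (validated at construction).
- *CI E-value.* Defined as exactly 1 when the interval contains the
  null: no confounding at all is needed to explain a non-significant
  interval.
- *Total confounding.* Flagged when B ≥ observed RR. Setting the bar
  at the observed RR (not at the E-value) is the reading consistent
  with the defining identity B(E, E) = RR: the worked example
  RR_UD = 3.00, RR_EU = 1.60 gives exactly B = 4/3, the observed RR.
- *Proportion explained.* The excess-risk reading is the only one
  compatible with B ≥ 1; it reproduces the published 71%/100%
  depression figures.
- *Unattainable targets.* Because B ≤ min(RR_UD, RR_EU), no
  complementary strength exists when the known association does not
  exceed the target; this is reported as "unattainable", not an error.

**Contours.** The curve `B(RR_UD, RR_EU) = b` is sampled log-spaced in
RR_UD on `(b, 10b]` (200 points by default; dense near the vertical
asymptote at RR_UD → b where RR_EU diverges). The symmetric marker
point (E, E) with `E = evalue(b)` is inserted explicitly so emitted
contours always contain the point figures annotate, independent of
grid resolution.

## Synthetic data

The study-level generator draws `se_i ~ U(se_range)`,
`μ_i ~ N(θ, τ²)`, `y_i ~ N(μ_i, se_i²)` — exactly the model the REML
stage assumes, so parameter recovery is a clean specification test of
the estimator (bias of the pooled log RR < 0.005 over 200 replicates
at k = 20, CI coverage 90–98%). It does not emulate small-study
effects, publication bias, correlated quantile contrasts, or
non-normal study effects; passing recovery tests therefore validates
the estimator, not the robustness of real-world pooling to those
violations.

The cohort generator is deliberately log-linear rather than logistic:
`U ~ Bern(p_u)`, `E | U ~ Bern(p_E·RR_EU^U)`,
`D | U, E ~ Bern(p_D·RR_UD^U·RR_true^E)`, so the generative parameters
are the very risk ratios the bounding factor consumes and the
bound-compliance test (crude RR ≤ RR_true·B within Monte-Carlo error)
checks B directly against its own data-generating mechanism. Defaults
`p_E = 0.2, p_D = 0.1, p_u = 0.2` keep all cell probabilities below 1
across the tested strength grid (RR up to 3 on either axis); configs
that would push a probability past 1 are rejected up front, naming the
offending product. Crude and stratified risk ratios use the standard
2×2 estimator with Wald log-scale intervals; a zero case count in an
exposure group triggers a flagged (never silent) 0.5 continuity
correction. The generator covers binary point-exposure confounding
only — no continuous confounders, no multiple simultaneous
confounders, no censoring or survival time (HR inputs are handled by
conversion, not simulation).

## Numerical choices and problem sizes

Full precision everywhere internally; rounding (2 dp for RRs, E-values
and B; whole percent for proportions) happens only at report-rendering
time. The REML optimiser is verified against a brute-force two-stage
grid search of the restricted likelihood (coarse step 1e−5 on τ²,
refined to 1e−8) and against an independent reference REML fit frozen
from a five-study fixture. Monte-Carlo test sizes — 50 random
meta-analyses for the oracle comparison, 200 replicates for recovery,
cohorts of n = 200,000 on a 4×4 strength grid for bound compliance —
were chosen to keep the default suite around a minute while leaving
Monte-Carlo standard errors well below the tolerances tested.

## Known limitations and reproduction caveats

Quantities published after rounding an unrounded pooled estimate do
not always recompute exactly from the printed inputs. With a pooled RR
printed as 1.14 but internally near 1.145: the E-value recomputes as
1.5395 (prints 1.54, not the published 1.55); the complementary
strength required of an overeating-type confounder with RR_UD = 1.49
recomputes as 1.60 (published: 1.62); and the food-insecurity scenario
(B = 1.1248) explains 89% of the point estimate as recomputed
(published: ~86%). The package always returns the closed-form value
computed from its actual inputs; users reproducing published tables
should feed unrounded estimates where available. The E-value and
bounding factor are bounds, not estimates: they state what a
confounder of given strength *could* do under the worst-case
configuration, and say nothing about whether such a confounder exists.
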