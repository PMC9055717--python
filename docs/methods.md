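# Methods

## The QEPS model

Individual growth is described as a sum of four bounded component
functions of gestational-age-corrected age `t` (years; `t = 0` at a
40-week term birth, conception at `-t0` with `t0 = 40*7/365.25 ≈ 0.767` y):

- **Q** (quadratic): `Q_u(t) = s(2 - s)` with `s = clip((t + t0)/TQ, 0, 1)` —
  rises from conception, plateaus at post-conceptional age `TQ`;
- **E** (exponential): `E_u(t) = 1 - exp(-kE (t + t0))` — saturating
  infancy growth;
- **P** (pubertal): logistic `P_u(t) = 1/(1 + exp(-(t - θP)/bP))` — the
  specific pubertal gain, amplitude `Pmax`;
- **S** (stop): basic (Q+E) *velocity* is damped by the sigmoid
  `σS(t) = 1/(1 + exp(-(t - θS)/bS))`, giving
  `QES(t) = ∫ (1 - σS)(dQ + dE)` and `S := QE - QES`.

The total curve is `QE + P - S ≡ QES + P`, so additivity holds by
construction and the height total is non-decreasing because every
component velocity is non-negative.  Height is modelled in cm.  Weight is
modelled on the `kg^0.5` scale (which makes the components approximately
additive for mass-like quantities) and the whole weight curve is scaled by
`(1 + WHF)`, a constitutional weight–height factor (0 = normal build,
positive = heavy, negative = lean).  BMI lives on the `kg^0.5/m` scale —
the square root of weight divided by height in metres — so conventional
BMI (kg/m²) is the square of the model value.  A ratio of curves is not
natively additive; the displayed decomposition defines *basic BMI* as
basic-only numerator over basic-only denominator and *puberty-specific
BMI* as total minus basic, so the plotted pair sums to the total exactly.

The functional forms above are this package's concrete choice of a
pluggable basis; they reproduce the qualitative structure (components
arising before birth, a bounded pubertal gain, growth ended by a stop) in
closed, invertible form.

**Landmarks.** Onset of the pubertal growth spurt is `AgeP5`, the age at
which 5% of `Pmax` has been attained — in closed form
`θP + bP·ln(0.05/0.95)`.  `AgeTPHV` is the age at peak velocity of the
total curve, found by a coarse scan plus bounded scalar refinement on
`[AgeP5 - 1, AgeP5 + 6]` (the window maximum can sit on an edge when the
spurt is weak).  Curves with fitted `Pmax` below 0.5 cm are flagged as
having no spurt and get no landmarks.

**Numerics.**  `QES` is evaluated as `QE` minus the stop-loss integral
`∫ σS (dQ + dE)`, computed by composite 8-point Gauss–Legendre quadrature
on panels ≤ 0.25 y whose edges include every evaluation age and the
Q-plateau kink; with these smooth integrands the quadrature is exact to
near machine precision, so the additivity and velocity/finite-difference
identities hold to ~1e-9.  Velocities are closed-form.

## Per-individual fitting

The model is linear in the three amplitudes, so fitting is variable
projection: bounded trust-region least squares over the six shape
parameters `(kE, TQ, θP, bP, dS = θS - θP, bS)` with amplitudes profiled
out by linear least squares (non-negative least squares if an amplitude
would go negative).  Five seeded multi-starts are jittered around a
heuristic start (`θP` from the steepest 3-point velocity); a perfect fit
short-circuits the remaining starts.  Bounds: `kE ∈ [0.2, 4]` 1/y,
`TQ ∈ [14, 26]` y, `θP ∈ [7, 18]` y, `bP, bS ∈ [0.25, 2.5]` y,
`dS ∈ [0.5, 8]` y.  Everything is deterministic given the seed.

The weight fit runs on `sqrt(weight)`; its shape search starts at the
fitted height shape, and the pubertal timing parameters `(θP, bP, θS, bS)`
are shrunk toward the height values by a ridge of weight λ = 0.006, sized
so the penalty contributes roughly a tenth of the data sum of squares at
default noise.  This keeps weight timing identified on sparse annual data
while letting a genuine timing offset (≈ half a year in the synthetic
cohorts) be recovered to well within 0.15 y.

**Cohort-level empirical-Bayes pass.**  A single growth curve measured
with 0.4 cm noise does not identify all nine parameters: the linearised
fit has a likelihood ridge along which `Pmax` trades against `bP`, `θS`
and `bS` (correlations ≈ ±0.97; unconstrained `Pmax` SD would be ~70%).
`fit_cohort` therefore refits each subject with a ridge pulling the weakly
identified shape parameters toward per-sex prior centres:

- centres for `kE`, `TQ`, `bP` come from a cohort-pooled joint fit (one
  shared shape, per-subject pubertal midpoints free, amplitudes profiled,
  sparse-Jacobian least squares) — these average well across subjects;
- centres for the stop phase (`dS = 2.2` y for height, 2.4 y for weight;
  `bS = 1.1` / 1.0 y) are fixed at field-typical maturation tempo, because
  the stop is too weakly identified for a data-driven centre even when
  pooled (basic growth ends a couple of years after the pubertal midpoint,
  over about a year's width);
- prior widths (`kE` 0.05, `TQ` 0.4 y, `bP` 0.06 y, `dS` 0.15 y, `bS`
  0.10 y) are sized to the plausible inter-individual spread of each
  parameter;
- penalty weights scale with the cohort's median residual rmse, so the
  shrinkage vanishes on noise-free data and individual `θP` (the pubertal
  timing signal) is never penalised.

On the default synthetic conditions (200 subjects/sex, 0.4 cm height
noise, the standard visit schedule) this pipeline recovers `AgeP5` with a
median absolute error of ≈ 0.07 y and `Pmax` to ≈ 3% median relative
error; `fit_height` alone recovers noise-free curves to machine precision.

**WHF estimation.**  Per sex, ordinary least squares maps
`[1, hQ, hE, hP]` to the fitted weight amplitudes across the cohort.  A
subject's WHF is the mean, over ages 2–18 y, of its own sqrt-weight curve
divided by the *typical* curve (predicted amplitudes with the subject's
own weight shape), minus one.  The linear map is rescaled by the cohort
mean ratio, so cohort-mean WHF is exactly zero and a subject constructed
exactly on the stored relation has WHF = 0 to machine precision.

**Cohort cleaning.**  Reference-population eligibility requires GA 37–43
weeks.  Severe obesity is excluded by a configurable cutoff (+2.5 SDS
default) on the maximum childhood-window BMI SDS against a provisional
internal reference; every exclusion is logged with its trigger.

## References and SDS

References are built from fitted curves only (no residual measurement
noise, which is why their spread is smaller than that of raw
measurements).  At each grid age (step 0.1 y; chronological axis 3.5–20 y
so the childhood-BMI window from 3.5 y is scoreable, charts display
4–20 y; puberty-adjusted axis −4 to +10 y around each subject's AgeP5)
the empirical percentiles at normal probabilities for SDS −2…+2 are taken
across subjects and smoothed along age by Gaussian-kernel local-linear
regression (bandwidth 1 y on the chronological axis, 0.5 y on the
puberty-adjusted axis); shared kernel weights keep the percentile order,
with an explicit monotonicity guard for edge effects.  SDS scoring is a
piecewise-linear map through the five percentile knots with linear tail
extrapolation at the adjacent tail spacing — an exactly invertible
quantile map, robust to the skewness of BMI distributions (no mean/SD
normality assumption).  BMI tables carry both `kg^0.5/m` and squared
`kg/m²` columns.

Subgroup curves are subject-level bootstrap medians (default 500 seeded
resamples, percentile 95% CIs), reported in native units and SDS; groups
under 5 subjects are flagged unstable.  Classification follows strict
inequalities: timing early/late beyond ±1.5 y of the analysis cohort's
own per-sex mean AgeTPHV, average within ±0.25 y; stature tall/short
beyond ±1.5 SDS at onset; childhood BMI high/low beyond ±1.5 SDS of the
maximum fitted BMI SDS over 3.5–7 y (girls) / 3.5–8 y (boys).

## The synthetic cohort generator

No real cohort ships with the package; a seeded generator emulates a
Scandinavian-style longitudinal growth study at the statistical level.  Defaults
(frozen after a one-off calibration against Swedish-style growth
milestones — birth size, 1 y, 7 y, late childhood, adult size):

- 1418 subjects (698 girls), GA truncated-normal 40 ± 1.2 weeks on
  [37, 43]; visits at 0, 0.25, 0.5, 0.75, 1, 1.5, 2 y then annually to 19
  plus 20 y; height noise SD 0.4 cm, weight CV 1.5% — typical clinic
  measurement error;
- mean curves: girls reach ≈ 167.5 cm / 62 kg, boys ≈ 180.5 cm / 71 kg;
  girls' pubertal midpoint 11.7 y (AgeTPHV ≈ 11.6), boys +2 y;
- a common size factor loads on height amplitudes (3.5%/SD) and more
  strongly on basic weight amplitudes (5.5%/SD) but only weakly on the
  pubertal weight amplitude (1.5%/SD): taller children are heavier *per
  height* in their basic build, while relatively short children carry
  relatively more puberty-specific BMI — the correlation structure behind
  the subgroup contrasts;
- a shared pubertal timing factor (SD 1.1 y) with the weight spurt
  systematically 0.5 y *before* the height spurt, plus small independent
  jitters; WHF ~ N(0, 0.07) scales the whole weight curve.

The weight pubertal component is deliberately narrow (bP 0.4 y) and the
weight stop follows its midpoint by 2.2 y: the pubertal weight (fat-like)
gain is concentrated early, and the later adolescent weight gain rides on
basic growth.  This is what makes BMI rise before the height spurt and
the aligned total-BMI median undulate — rise, local maximum two to three
years after onset, shallow dip — as height momentarily outpaces weight.

**What the generator does not emulate.**  Real cohorts have missed
visits, irregular ages, secular BMI drift, skewed (non-lognormal) weight
distributions, and measurement error that varies with age; the generator
has none of these, so passing tests demonstrate the machinery is correct
under the stated statistical conditions, not that the numerical accuracy
would transfer unchanged to clinical data.  The concentrated pubertal
weight component implies a peak weight velocity (~17 kg/y) well above the
~9 kg/y of real adolescents: a stylised consequence of packing the
early-pubertal weight gain into a single logistic while the model's basic
component carries the rest.  A two-component pubertal weight model would
relax this but is out of scope.

## Design choices where the ground was open

- Stop mechanism as velocity damping (guarantees monotone QES and a clean
  additive `S`), evaluated by near-exact quadrature rather than a cached
  grid.
- WHF as an age-constant multiplicative factor, estimated from curve
  ratios on 2–18 y.
- SDS via empirical quantile mapping rather than mean/SD.
- Alignment on the age axis at AgeP5 (the attained-height axis is a
  recorded alternative reading; the prospective chart workflow shifts an
  individual's points by their onset age, consistent with a
  time-from-onset x-axis).
- Acceptance-level population properties (reference calibration,
  alignment sharpening, subgroup signs, undulation) are computed from the
  generator's true parameter curves; the fitting pipeline is validated
  separately by the recovery and WHF checks.  Problem sizes used: 400
  subjects per sex for population properties, 200 per sex for noisy
  parameter recovery, 1000 random parameter sets for algebraic
  identities.

## Known limitations

- The basis is one concrete realisation of the Q/E/P/S structure; other
  published parameterisations will differ in the exact component split
  (though not in total-curve fit quality).
- Per-subject stop parameters are only weakly identified at clinical
  noise levels; their estimates are shrunken and should not be
  over-interpreted individually.
- BMI component references inherit the non-additivity of ratios; only the
  displayed total/basic/P-specific triple is exactly consistent.
- The LMS comparison is a variance-ratio hook against an externally
  supplied table, not an LMS implementation.
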