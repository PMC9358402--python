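# Methods

## Model and assumptions

The axis is modelled as three fast hormone balances (TRH, TSH, free T4) and
two slow gland-mass balances (thyroid functional mass `T`, pituitary
thyrotroph functional mass `P`); see the README for the equations.  The key
structural assumptions are:

- hormone secretion is proportional to the functional mass of the secreting
  gland (doubling thyroid mass doubles TH output at fixed TSH);
- TSH-receptor activation (by TSH or by Graves' autoantibody `Ab`, expressed
  in TSH-equivalent units) drives both TH secretion and thyroid growth, so
  `Ab` enters inside `f(TSH + Ab)` in the TH equation and the thyroid-growth
  equation — the two places the receptor acts.  This placement is the one
  consistent with the derived clinical-Graves threshold
  `Ab > a_T/b_T + b_P a_TH k_T/(a_P b_TH)` (scaled: `AB > 1 + K_T`);
- TH suppression of TSH/TRH secretion uses `1/TH` kernels, the large-TH limit
  of a Michaelis–Menten form.  A saturating suppression kernel
  (`k_T4/(k_T4+TH)`, field `th_suppression="michaelis"`) is provided; it
  flattens the fast TSH–TH log–log slope below 2 and is used by the TRH-test
  machinery;
- gland growth saturates logistically at carrying capacities `1/k_T`,
  `1/k_P` (hypertrophy and hyperplasia are not distinguished);
- no T3/deiodinase compartment, no circadian or pulsatile secretion, no
  levothyroxine pharmacokinetics beyond the constant source `b_30`.

## Parameters, units, defaults

Time is in days throughout.  Default removal rates are reciprocal hormone
lifetimes: `a_TRH = 1/(6 min)`, `a_TSH = 1/(1 h)`, `a_TH = 1/(7 d)`, and
gland turnover `a_T = a_P = 1/(30 d)`.  The reciprocal convention (rate =
1/lifetime, not ln2/half-life) is the default because it reproduces the
reference simulations this model family is calibrated against;
`half_life_convention="log2"` switches to `ln2/t½`.  Production rates are
never set directly: `calibrate_production_rates` solves all five of them so
that a healthy set point — FT4 = 15 pmol/L, TSH = 1.5 mIU/L, `T = P = 1`,
TRH normalised to 1 (TRH units are arbitrary and TRH only reaches outputs
through TSH) — is an exact fixed point for the chosen capacities.

The slow subsystem is governed by four dimensionless groups, computed by
`scale_parameters`: `K_T = k_T·T₀` and `K_P = k_P·P₀` (capacities in units
of the capacity-free steady masses `T₀`, `P₀`), `AB = Ab·b_T/a_T` (antibody
in units of the capacity-free steady TSH) and `B30 = b_30·a_P/(a_TH·b_P)`
(external T4 in units of the steady TH production).  The denominator group
of `B30` is fixed by dimensional analysis — `b_30/(a_TH·TH₀)` is the unique
combination that makes the scaled quasi-steady TH equation read
`th = t(tsh + AB) + B30`.  `KX2 = k_T4/TH₀` parameterises the saturating
suppression kernel and is 0 for the default `1/TH` kernel.

Scenario conventions: the disease scenarios state their capacities in the
*scaled* sense (Hashimoto: `K_P = 1`, thyroid capacity off; Graves:
`K_T = 1`, pituitary capacity off), because a raw `k_P = 1` with a unit
steady-state mass would annihilate the growth term.  `capacities_from_scaled`
inverts `K_T = x/((1−x)(1−y))`, `K_P = y(1−x)/(1−y)²` (with `x = k_T·T_set`,
`y = k_P·P_set`) for the raw capacities; `K_P = 1` gives
`k_P = (3−√5)/2 ≈ 0.382` (capacity ≈ 2.6× the healthy mass), `K_T = 1`
gives `k_T = 1/2`.  Region classification and staging sweeps instead use
literature gland capacities of 5.5× (thyroid) and 5.3× (pituitary) the
healthy volume, and laboratory reference ranges TSH 0.5–5 mIU/L,
FT4 10–20 pmol/L.

## Treatment calibration

Treatment parameters are root-found on the steady-state map, never
hand-tuned.  For Hashimoto's the levothyroxine source solving
`steady-state TH = 15 pmol/L` under the diseased parameters is
`b_30 = a_TH·15` — at that dose the residual thyroid cannot satisfy its own
growth balance and atrophies, so replacement carries the axis alone.  For
Graves' the treated state has the antibody cleared; the root-found
antithyroid `b_TH` then lands on the basal value, because with `Ab = 0` the
steady TSH is `tsh_set` exactly at basal `b_TH` (the calibration objective
is degenerate in the direction of further reduction: any `b_TH` restores the
hormone set point, only the steady thyroid size changes).  The hysteresis
loop is produced by the slow thyrotroph recovery either way.

## Quasi-steady-state layer and numerics

Nullclines, fixed points and region maps treat the hormones as equilibrated
at fixed masses (minutes-to-days vs. a month of timescale separation).  The
scaled QSS system `th = t(tsh+AB)+B30`, `tsh = p(1+KX2)/(th(KX2+th))` is
solved by bracketed Brent iteration in `log th` (closed form
`th = (t·p)^{1/3}` when unperturbed); the general nullclines are obtained by
root-finding the slow growth-balance residuals rather than transcribing
their typeset closed forms, with the simple-case forms
`p = t²/(1−K_T t)³` and `t = (1−K_P p)³/p` kept as regression anchors
(agreement to 1e−8 is a test).  Stability is classified on the 2-D slow
Jacobian (finite differences, relative step 1e−7) and spot-checked against
the full 5-D Jacobian.  Fixed-point searches multi-start a Powell-hybrid
root solver in log-mass coordinates and accept roots with residual < 1e−8;
the `P = 0` and `T = 0` boundary branches are added analytically.

Integration uses LSODA with `rtol = 1e−9` and per-component `atol` of
1e−12 times the set-point scale (cohort simulations relax to `rtol = 1e−7`);
event schedules restart the solver at each parameter change so
discontinuities are placed exactly.  Because thyroidectomy drives TH toward
zero, the 1/TH terms clamp TH at a floor of 1e−9 times the set point inside
the right-hand side (hits are counted and logged).  Steady-state detection
uses a scaled rate threshold of 1e−8/day; curve-membership uses relative TSH
residual < 1e−6.

Thyroidectomy timing is reported as the 1/e relaxation time of TH toward its
within-horizon extremum: with a zero thyroid remnant TH decays exponentially
and has no interior minimum, so "time to reach the minimum" is only
meaningful as a relaxation timescale (≈ 1/a_TH = 7 days).

## Thyrotroph-mass estimators

The TRH-test estimator inverts the Michaelis–Menten TSH equation under a
saturating TRH bolus.  The secretion rate is recovered from the measured
rise with a turnover correction; the default inverts the exponential decay
exactly, `S = a_TSH(TSH_stim − TSH_basal·e^{−aΔt})/(1−e^{−aΔt})`, because at
the conventional Δt ≈ 30 min the product `a_TSH·Δt = 0.5` is not small and
the first-order correction `ΔTSH = TSH_stim − TSH_basal(1 − a_TSH Δt)`
under-recovers P by ≈ 10% (both variants are exposed; the closure error of
each is itself under test).  `k_T4` defaults to the set-point FT4
(half-maximal suppression at health) and `k_TRH` to the set-point TRH; the
secretion scale `b_TSH` is fixed by basal consistency at the healthy set
point, so only relative masses are meaningful, as expected for a test that
would be calibrated per laboratory.  The hysteresis-ratio estimator
interpolates TSH on the two loop branches at a matched T4; the identity
`TSH₁/TSH₂ = P₁/P₂` holds to QSS accuracy (the residual is the hour-scale
TSH tracking lag, ~1% on the slow Hashimoto loop and up to ~5% on the
day-scale Graves onset transient) and requires a constant hypothalamic
input `u` — a mid-loop change of `u` measurably breaks it.

## Synthetic cohort: what it emulates, and what it does not

`cohort_synth` emulates the *structure* of HMO claims/lab extracts: per
patient an individual set point (lognormal, 10% CV on FT4 and TSH targets),
a disease ramp (Hashimoto: `a_T` rising linearly to a lognormal severity of
mean 5× over 200 days; Graves: `Ab` rising to 5× the set-point TSH over 100
days), sparse paired TSH/FT4 tests (Poisson, 8/year over 600 days),
diagnosis at the first noisy test beyond a threshold (TSH > 6 mIU/L
Hashimoto, < 0.3 mIU/L Graves), a medication-purchase date within ±30 days
of diagnosis, treatment as a 21-day levothyroxine up-titration (Hashimoto)
or antibody clearance (Graves), and multiplicative lognormal assay noise
(10% TSH, 5% FT4).  Pre/post labeling follows the 90-day lookback rule:
onset is the earlier of diagnosis and medication purchase, the purchase
counting only if within 90 days before diagnosis; patients with no
treatment events are entirely pre-treatment.  All randomness flows from one
seeded generator, so tables are bit-reproducible.

What it does not emulate: age/sex structure, assay censoring at detection
limits, dose adjustments and non-adherence, co-morbidities, and
within-patient set-point drift.  Tests passing on this generator therefore
establish that the *pipeline* (phase splitting, quantile binning with
SEM, log-linear slopes) recovers structure that is present by construction —
they do not validate the model against real records, whose slopes and bin
shapes reflect many factors the generator omits.  The published
population slope values are for that reason not used as targets anywhere.

"Semi-equal-sized" TSH bins are quantile bins (`pandas.qcut`) with tied
discrete values collapsed into fewer bins (a warning reports the reduction);
slopes are ordinary least squares of log₁₀(TSH) on FT4 (the log base of the
clinical "log-linear" convention; configurable).

## Design choices that were genuinely open

- The two printed forms of the TSH(T4) curve amplitude are reconciled as
  `α = TSH₀·T40²/(P₀·k_P)`, the unique grouping that equals
  `A = b_TRH b_TSH u/(a_TRH a_TSH k_P)` under substitution of the
  capacity-free steady states; `curve_from_setpoint` exposes this set-point
  form with the pituitary capacity as a fold of the healthy mass (5× for the
  non-parameterised clinical curve).  Note the two conventions for the
  zero-crossing: `B = b_P/a_P` is the *capacity-free* steady FT4, which with
  a finite pituitary capacity exceeds the calibrated set-point FT4 by
  `1/(1−k_P)`; both are accessible (`tsh_of_t4_curve` vs
  `curve_from_setpoint`) rather than silently merged.
- Clinical composites for discordant hormone pairs: abnormal T4 with normal
  TSH is labelled `normo-TSH/abnormal-T4`; abnormal T4 with abnormal TSH is
  clinical (by the T4 side); abnormal TSH with normal T4 is subclinical.
- The thyroidectomy scenario runs with the pituitary capacity active
  (`K_P = 1`), since an asymptotic maximum for P presupposes one.

## Known limitations

- The analytic layer (scaled groups, nullclines, threshold, curve) assumes
  the linear regulation function; the saturating variant is integrated
  numerically but excluded from those cross-checks.
- Stability classification trusts the 2-D slow reduction; it is spot-checked
  against the 5-D Jacobian but not proven equivalent in all corners of
  parameter space.
- Cohort simulations use problem sizes of tens-to-hundreds of patients with
  8 tests/year — adequate for direction and recovery checks, far below the
  ~10⁵-test scale of real registry analyses, so binned curves carry visibly
  larger SEMs.
- Only relative thyrotroph mass is estimable from blood tests; the absolute
  scale depends on the `b_TSH`/Δt calibration convention.
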