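# Methods

This note records the modelling and numerical choices behind `scanbias`, in
the spirit of a statistical software methods appendix.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The bias construct

Expected value `E` is the gestational age (GA) at scan time in days, fixed
by the due date from the dating scan.  Observed value `O` is the GA implied
by a biometric measurement through a growth-standard curve — the number the
machine displays in the measurement box beside the caliper reading.  A saved
measurement is *at risk of expected-value bias* when the operator fixates on
the measurement box at any time during caliper adjustment, operationalised
as the half-open interval `[t_box_appear, t_save)`.  This is a *risk*
definition: a qualifying look flags the measurement as biased even if no
caliper motion follows, because the opportunity to steer existed.  The
"before" state is the caliper value in force at the start of the *first*
qualifying fixation (not the initial automatic placement, which is retained
separately for auxiliary analyses); the "after" state is the saved value.

With signed deviations `d_before = O_first_look − E` and
`d_after = O_saved − E` (days), each saved measurement gets exactly one
adjustment class:

* **toward** — `|d_after| < |d_before|` beyond tolerance,
* **away** — `|d_after| > |d_before|` beyond tolerance,
* **unchanged** — the two agree within 0.25 day (the measurement box
  displays GA in weeks + days, so sub-day wiggle is display noise;
  configurable),
* **unbiased** — no qualifying fixation.

`adjustment_days = |d_before| − |d_after|` is positive when the measurement
moved toward the expected GA.

## Fixation detection

A fixation on the measurement-box AOI is a dwell of ≥ 100 ms (a standard
lower bound for an eye fixation), where interruptions of ≤ 400 ms — whether
the gaze left the rectangle or the tracker lost the eye — are bridged first,
and the duration threshold is applied to the *merged* episode
(merge-then-threshold; the alternative order is achievable by composing the
primitives but is not the default).  Gaze trackers emit point samples, so a
sample-to-interval rule is required: each sample occupies the half-open
interval between the midpoints to its temporal neighbours; the first sample
starts at its own timestamp and the last ends at its own timestamp.  A
sample is in-AOI iff it is valid, inside the rectangle (left/top inclusive,
right/bottom exclusive) and within the AOI's active interval; invalid
(tracker-loss) samples count as out-of-AOI and participate in the 400 ms
merge rule like any other interruption.  The implementation is verified
against an independent brute-force oracle (nearest-sample rasterization on a
0.5 ms grid followed by run-length analysis) on 1000 random streams spanning
30–120 Hz.

## Growth standards

The scanner's proprietary curve tables are not public, so the package ships
a clearly labelled default coefficient set (`standards/hadlock.yaml`) and
treats everything as configuration: per plane a GA-from-measurement
polynomial (GA in weeks as a polynomial in the measurement in cm), its valid
GA range in days, and a root-finding bracket; one EFW formula block; one
EFW-for-GA reference block; centile cutoffs.  Swapping YAML swaps standards;
no coefficient is hard-coded in logic.

* **Direction and inversion.**  The configured closed form is
  GA-from-measurement — the direction the machine evaluates for its display.
  The forward curve measurement-from-GA (needed by the simulator) is its
  numerical inverse via Brent root-finding with `xtol = 1e-6` cm, far below
  the 0.01-day tolerance target for any plausible curve slope.  All default
  polynomials are strictly increasing over their brackets, so the round-trip
  identity holds to < 0.1 day across the valid range (tested on 1000-point
  grids per plane).
* **Out-of-range (OOR).**  When a measurement implies a GA outside the
  plane's tabulated range the polynomial is evaluated anyway — extrapolated,
  never clamped, never missing — and the result carries an `out_of_range`
  flag downstream.  Polynomial evaluation is continuous, so there is no jump
  at the range boundary.
* **EFW.**  Hadlock-type three-parameter formula,
  `log10 EFW(g) = 1.326 − 0.00326·AC·FL + 0.0107·HC + 0.0438·AC + 0.158·FL`
  (cm).  Within the configured physiologic domain (HC 80–450 mm, AC
  80–480 mm, FL 15–110 mm) the formula is strictly increasing in each
  argument (the cross-term would only flip the AC derivative above
  FL ≈ 134 mm, far outside the domain).
* **EFW-for-GA reference.**  `ln EFW` is modelled as a quadratic in GA
  (weeks) with constant SD 0.127 on the log scale (≈ a 12.7% coefficient of
  variation).  `Z = (ln EFW − μ(GA))/σ`, centile = `Φ(Z)·100`.  SGA/LGA
  cutoffs default to the 10th/90th centile with *strict* inequalities, so a
  centile exactly at a cutoff classifies AGA.  Whether the scanner's own
  Z-scores used a log transform is unknown; the log-normal choice keeps Z
  monotone in EFW and the reference swappable.

GA is handled in days internally; weeks + days appear only at presentation.

## Candidate sets and EFW impact

For each scan and plane, the *candidate set* contains, for every biased
episode, both the first-look and the saved value, and for every unbiased
episode the saved value only.  Intermediate-look values are excluded by
default (the before/after framing is a two-point comparison); a config flag
exists for logs that record every look.  The lowest possible EFW combines
the per-plane minima, the highest the maxima; discordance is
`100·(EFW_max − EFW_min)/EFW_max` (twin-discordance convention; a
pairwise-mean denominator is available).  Z-scores for both bounds are taken
at the scan's expected GA, and a scan *swings* when the two bounds classify
differently (SGA↔AGA, LGA↔AGA, or — possible in principle — SGA↔LGA,
labelled "other").  Scans missing a plane are excluded and counted.

Note one consequence of the candidate-set definition: a plane measured more
than once contributes *all* its saved values, so unbiased repeat variability
alone widens the EFW bounds.  The identity "an all-unbiased cohort has zero
discordance" therefore holds exactly when each plane has a single saved
value, and the tests construct that case explicitly (no looks, no repeats).

## Statistical analysis

All standard machinery comes from scipy/statsmodels; the package adds the
domain layer, not the tests themselves.

* **Incidence table** (per plane + total): saved n, repeat n, measurements
  per scan (mean ± SD over scans, scans without the plane counting zero),
  % biased, % toward, % away, mean ± SD adjustment.  Percentages use all
  saved measurements as denominator — the published toward/away figures only
  sum below 100% if the remainder (unchanged + never-looked) is implicit —
  and the biased-only denominators are reported alongside.  The mean
  adjustment is likewise reported over biased measurements and over all
  saved ones (unbiased contributing zero), since the published table is
  ambiguous about its denominator.
* **Before/after**: among biased measurements, paired *t* and Wilcoxon
  signed-rank on `|d_before|` vs `|d_after|`, and the same paired tests on
  the *signed* deviations.  Both are reported deliberately: the absolute
  comparison answers "did measurements end closer to the expected GA", while
  the signed comparison ("did the mean observed GA shift") is the quantity
  whose expectation is exactly zero when a look merely re-jitters the
  caliper — under the simulator's generative model with `β = 0`,
  `d_after − d_before` is mean-zero noise, whereas `|d_after| − |d_before|`
  has strictly positive mean for any nonzero jitter (additive noise escapes
  `|d|` more often than it returns).  Null-calibration checks therefore use
  the signed paired *t*.  Variance equality before vs after uses Levene's
  test with median centering (Brown–Forsythe), pooled across planes with
  per-plane breakdowns.
* **Repeats**: within a scan, the first saved measurement of a plane is the
  original and every later one a repeat; each saved measurement contributes
  its own `|d_after|` to the repeated / not-repeated groups (the grouping is
  a genuine modelling choice — alternatives such as excluding the final kept
  measurement can be built from the flags).  Groups compared by
  Mann–Whitney *U*.
* **Adjusted models**: OLS of `d_after` on `d_before` + maternal BMI +
  operator experience (biased measurements), and a type-II ANOVA of
  `|d_after|` on repeat status + the same covariates.  Rank deficiency
  raises an explicit singular-design error; missing covariates are dropped
  listwise with the count reported; a cohort with no repeats degrades the
  ANOVA to an explicit marker rather than failing the model set.
* **Proportion CIs**: Wald and Wilson 95% intervals (statsmodels), method
  recorded in the output.  No multiple-testing correction is applied
  (per-comparison reporting, flagged in output metadata); p-values are
  reported in full precision and rounded to 4 decimals in `tests.json`.

## The simulator

The generator encodes the behavioural model the analysis assumes — look,
adjust toward the expected value, re-measure when far from it — with every
parameter explicit and seeded (`numpy.random.default_rng`; identical config
+ seed gives byte-identical logs and streams).

Per scan: `E ~ floor(Uniform(200, 285))` days (third-trimester window with
mean ≈ 34.6 weeks), a fetal-size offset `δ_scan ~ N(0, σ_fetal)` shared by
all planes, and per plane an acquisition offset `ε_plane ~ N(0, σ_plane)`
giving the true GA-equivalent `T = E + δ + ε`.  Each measurement attempt
draws caliper noise `η ~ N(0, σ_meas)`: `O₀ = T + η`.  With probability
`p_look` a fixation of 250–600 ms is scripted inside the box AOI during the
adjustment window and the saved observation becomes
`O₁ = O₀ + β(E − O₀) + ν`, `ν ~ N(0, σ_adj)`; otherwise `O₁ = O₀`.  If
`|O₁ − E| > τ`, a repeat attempt follows with probability `p_rep` (up to 3),
re-drawing `η` but keeping `T`.  GA-equivalents map to millimetres through
the growth standard's forward curve, so bias is defined on the GA scale
where `β` is interpretable in days (an mm-scale variant is available by
flag).

Defaults (the simulated study conditions): 272 scans, 16 operators,
`σ_fetal = 9`, `σ_plane = 5`, `σ_meas = 4` days — a combined
observed-deviation SD of ≈ 11 days, producing the one-to-two-week spreads
typical of third-trimester deviation plots; `p_look = 0.914`; `β = 0.3`,
which at that deviation SD yields mean toward-adjustments of ≈ 2–3 days;
`σ_adj = 1` day, the weeks+days display resolution — kept deliberately small
relative to the deviation SD because post-look jitter comparable to the
deviation spread would by itself push measurements away from `E` on average
and destroy the toward/away symmetry that must hold at `β = 0`; `τ = 8`
days, `p_rep = 0.7`; BMI ~ N(25.8, 5.3²) kg/m², operator experience ~
Uniform(0.3, 14) years.  These magnitudes are illustrative study conditions,
not published values.

Gaze streams are sampled at 60 Hz by default: background gaze wanders
outside the box rectangle; scripted fixations place samples inside it;
distractor glances of 30–80 ms (hard negatives) and tracker-loss gaps of
50–300 ms are placed at least 600 ms clear of scripted fixations so the
400 ms merge rule can never bridge a negative into a real look.  Under the
midpoint occupancy rule a glance can stretch by up to one sample period, so
the sub-100 ms guarantee for an 80 ms distractor holds for rates ≥ 50 Hz;
at the default rate the pipeline recovers the scripted look indicators with
zero false positives and zero false negatives, which the tests assert
exactly.

What the simulator does **not** emulate: real caliper trajectories (values
jump once, after the look, rather than drifting), operator-specific bias
styles, fatigue or learning, plane-difficulty asymmetries (the observed
cohort repeated AC far more often than HC/FL), image-quality-driven
re-acquisition, or correlated gaze dynamics (saccade kinematics, smooth
pursuit).  Passing tests therefore demonstrate that the pipeline measures
the modelled mechanism correctly — not that real scans satisfy the model.

`β` is recovered as the OLS slope of `(d_before − d_after)` on `d_before`
among biased measurements: under the model `d_after = (1−β)·d_before + ν`,
so the slope is `β` and the intercept absorbs nothing under correct
specification.

## Problem sizes in the test suite

The suite exercises: 1000 random streams for the fixation oracle; 1000-point
grids per plane for curve inversion; 300-scan cohorts for β recovery
(β = 0.5 → β̂ within ± 0.1), null symmetry (β = 0 → toward/away within 5
percentage points) and Levene power; and 100 replicate 40-scan cohorts for
null calibration of the signed paired *t* (rejection count within the
central 99% binomial band around 5%).  Replicate cohorts use the simulator's
scripted-fixation fast path, which the gaze-recovery tests show to be
exactly equivalent to the raw-gaze path.

## Known limitations

* The default growth curves and EFW reference are labelled Hadlock-type
  defaults; they are not the (proprietary) tables of any specific scanner,
  so absolute GA/EFW values depend on the configured standard even though
  the bias statistics (built on differences of observed GAs through the same
  curve) are far less sensitive to the choice.
* The bias definition captures *risk* of bias; it cannot distinguish
  steering from legitimate plausibility checking, and an adjustment away
  from `E` may itself be biased (e.g. an expectation of macrosomia).
* Event logs are assumed already extracted; video OCR, plane-quality
  scoring and eye-tracker calibration are out of scope.
* The repeat-group and adjustment-denominator conventions follow one
  defensible reading of ambiguous published summaries; both alternatives
  are surfaced in the outputs so readers can compare.
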