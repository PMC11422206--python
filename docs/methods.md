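# Methods

This note documents the models, conventions and numerical choices behind
`nirsvot`, in the package's own terms.  Everything quantitative stated here
is computed by the test suite or by `scripts/acceptance.py`.

## Protocol model

A session is a contiguous sequence of half-open phases
`[t_start, t_end)`: baseline (900 s), then three cycles of occlusion
(420 s) and reperfusion (600, 600, 1200 s), 4560 s in total at 10 Hz.
Cuff inflation and deflation by a manual sphygmomanometer take several
seconds; the package models and segments this as a linear ramp of
`cuff_ramp_s = 6 s`.  Cuff pressure per group is either absolute
("50", "250") or individualized relative to systolic blood pressure
("SBP+50").

## Synthetic cohort generator

The generator produces recordings with the statistical and kinetic
structure the analysis assumes, with closed-form ground truth.  All shapes
below are modelling choices of this package, selected for smoothness,
parsimony and the qualitative phenomenology of resting VOT data; they are
not fitted to any dataset.

**Occlusion completeness.**  `c = 1 / (1 + exp(−(P − SBP)/k))` with width
`k = 10 mmHg`: ~0 for a 50 mmHg venous-only cuff on a normotensive arm,
0.5 at systolic pressure, ~0.99 at SBP + 50, ~1 at 250 mmHg.  A logistic
smoothly interpolates the venous→arterial transition and makes the
dose-response monotone by construction.

**Occlusion kinetics.**  HHb deviation `A·r(t)·(1 − e^(−t/τ_deoxy))` with
amplitude `A = a_ven + c·a_art` and the linear inflation ramp `r(t)`;
O₂Hb mirrors it with negative sign (total hemoglobin is conserved during
arterial occlusion).  Defaults `a_ven = 8`, `a_art = 22` device units and
`τ_deoxy = 160 s` give a suprasystolic HHb plateau near 28 units and a 63%
rise time near 140 s over a 7-min occlusion — the scale of published
resting-forearm values.  The rate is deliberately *not*
pressure-dependent: only the amplitude scales with `c` (a known departure
from real venous-only kinetics, which saturate faster).

**Reperfusion and hyperemia.**  The plateau deviation decays as
`exp(−x_eff/τ_reoxy)` with `τ_reoxy = 20 s`, where
`x_eff = ∫ min(x/ramp, 1) dx` is elapsed time weighted by the deflation
ramp — this keeps the trace C¹-smooth at deflation (flow, hence washout,
resumes gradually).  Post-occlusive reactive hyperemia is an alpha
function `(x/t_p)·e^(1 − x/t_p)` (`t_p = 25 s`), also ramp-weighted, added
to the O₂Hb pool.  Its amplitude is calibrated by a bracketed 1-D solve on
the closed-form model so that the **net** TSI spike above baseline equals
`h_amp·c` (`h_amp = 10%`); without the calibration the overshoot would be
partially cancelled by the still-recovering occlusion deviation.
Smoothness at deflation matters quantitatively: derivative discontinuities
there are turned into ~0.1% ringing on the occlusion extrema by the
order-10 zero-phase filter.

**Saturation channel.**  The emitted channels are absolute pools
(`o2hb = 65 + Δ`, `hhb = 35 + Δ`, baseline TSI 65%), and TSI is always
`100·o2hb/(o2hb + hhb)` of those pools — so TSI is bounded in [0, 100] and
the derived-channel operation reproduces it exactly.

**Noise, drift, variability.**  White Gaussian noise (`σ = 0.68` units per
concentration channel, chosen so raw baseline TSI SD ≈ 0.5%, plausible for
the device class) and a slow common drift (`10⁻⁴ units/s`) act on the raw
pools and propagate into TSI.  Cohorts draw per-subject SBP from
Normal(118, 9) mmHg, a per-subject response-amplitude factor
(CV 12%) and a per-session factor (CV 5%), emulating between-visit
variability at the amplitude CVs typical of reported group summaries.
Two sessions are independent draws.  All randomness flows from one seed;
identical seeds give bitwise-identical datasets.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: pressure-dependent kinetic *rates*, adipose-layer
optics and probe-coupling artifacts, movement transients, HHb undershoot
during hyperemia, autonomic oscillations (only white noise + linear drift),
and device-specific spatially-resolved TSI (the simulated TSI is exactly
the two-pool saturation).

## Signal conditioning

* Filter: Butterworth low-pass, designed order 10, cutoff 0.8 Hz, applied
  forward–backward (`sosfiltfilt`), so the effective magnitude response is
  the squared design response and group delay is zero.  Odd-reflection
  padding of 3× the filter length bounds edge transients; shorter records
  are rejected.  DC gain is exactly 1.
* Normalization: subtraction of each channel's mean over [150 s, 750 s)
  (the central ten baseline minutes).  TSI is normalized the same way as
  the concentrations, so all downstream signals are deviations from rest.
  Re-normalizing is a guarded error, not a no-op.
* Input: delimited text with configurable column mapping; a device TSI
  column is used when present, otherwise TSI is derived from the
  concentration pools (logged).  Gaps ≤ 0.5 s are linearly interpolated;
  longer gaps fail the recording.  Files are written with `%.17g` floats
  so write→read round-trips doubles exactly.
* Concentration units are carried opaquely as "device units".

## Event segmentation conventions

* **Curve bounds (10%)**: the peak is the largest absolute deviation from
  the local pre-event level (the series value at the window start); start =
  last time before the peak at or below 10% of the peak deviation, end =
  first such time after it, both linearly interpolated.  A curve that
  plateaus "ends" at the window end (flagged, still usable for slopes); a
  flat window is "no event".  The deoxygenation search starts
  `cuff_ramp_s` after inflation; the reoxygenation curve is referenced to
  the occlusion-end level and searched from deflation.  Ties at equal
  extrema break to the earliest time.
* **τ₆₃**: time from occlusion start until the channel first attains 63%
  of its extreme deviation in the occlusion window (downward for TSI,
  upward for HHb), interpolated between samples.
* **Hyperemia spike**: maximum of normalized TSI within 120 s of
  deflation.  A spike below `PORH_MIN_SPIKE = 0.2%` TSI (under the ~0.5%
  baseline noise) is flagged "no hyperemia": on a near-flat trace the
  spike-relative crossing times are ill conditioned, and venous-only
  cycles legitimately have no hyperemia.
* **PORH window**: from the zero-crossing nearest to the spike on its left
  (fallback: window start, flagged) to the first drop below 37% of the
  spike value (fallback: phase end, flagged); the PORH AUC integrates
  normalized TSI between these interpolated bounds.  The PORH rise time is
  measured from the reoxygenation-curve start to 63% of the spike
  amplitude above the occlusion-end level — one consistent reading of a
  "PORH time constant", stated here as an interpretation.
* **AUC sign convention**: occlusion AUCs integrate the baseline-normalized
  signal with sign retained (negative for TSI/O₂Hb deoxygenation, positive
  for HHb), *not* |x| — consistent with reporting negative TSI AUCs.
* Cycle averaging is the unweighted mean over non-flagged cycles; a
  parameter flagged in all three cycles becomes a missing value (logged).

## Statistics

* Outliers: one pass of mean ± 2 SD (sample SD), computed on the full
  input, per parameter × group × session; deliberately not iterated.
* Routing: nonparametric iff any group fails Shapiro–Wilk or the groups
  fail Levene's test (center = mean) at α = 0.05; a zero-variance group
  forces the nonparametric route.  With two within-subject levels
  sphericity holds trivially and is reported as such.
* Parametric route: one-way ANOVA (scipy), mixed group × session ANOVA
  (pingouin), pairwise independent t-tests, Cohen's *d* with the two-group
  pooled SD and the conventional 0.2/0.5/0.8 magnitude labels.  Design-wide
  error-term variants of *d* exist in other software and can differ
  substantially from the pairwise pooled-SD value; this package reports
  only the pairwise convention and labels it as such.
* Nonparametric route: Kruskal–Wallis with tie correction; Dunn's z on
  pooled mid-ranks with tie adjustment for ≥3 groups (Mann–Whitney, exact
  for small tie-free samples, for 2); rank-biserial
  `r = (#(a>b) − #(a<b))/(n_a·n_b)`, the dominance form equivalent to
  `2U_a/(n_a·n_b) − 1` with mid-rank ties: −1 when every b exceeds every a.
* Bonferroni: corrected p = raw p × number of pairs, capped at 1.
  Two-sided throughout; α = 0.05.

## Validation design and problem sizes

Two independent routes compute every parameter: the discrete pipeline
(sampled at 10 Hz, filtered, threshold-based) and continuous-model oracles
(brentq root-finding, quadrature and dense OLS on the closed-form
deviations), which never touch the sampled path.  On a noiseless
three-group cohort (n = 12/group, two sessions, 216 cycles) the suites
require agreement within one sample (0.1 s) for event times and 0.1% for
extrema/AUCs, with the channel response amplitude as the relative floor
for parameters whose true value is 0.  Slopes get the looser of 0.1% and
the slope change a one-sample shift of the detected curve start would
produce, since the 10%-threshold start is itself resolved to one sample.
Under default noise, 100 seeded single-session replicates must keep every
parameter's mean within 5% of the noiseless truth on the same scale.
Statistical calibration uses 1000 null replicates (type-I) and 200
programmed-separation replicates (three pooled SDs between G1 and the
suprasystolic groups at n = 12); rank-biserial is checked against exhaustive
pairwise-dominance enumeration for group sizes up to 8.  These sizes keep
the default test run to roughly a minute while leaving the Monte-Carlo
error well inside each band (the type-I test uses 4000 replicates for that
reason).

## Known limitations

* The generator's kinetic rates do not vary with cuff pressure, so
  rate-based contrasts between venous and suprasystolic groups (faster
  saturation under venous pooling) are outside what the synthetic cohort
  can demonstrate.
* The PORH "time constant" definition above is one of several plausible
  readings; comparisons across packages should check conventions.
* Cohen's *d* from the pairwise pooled SD is not comparable to
  design-wide-error-term *d* values produced by some ANOVA software.
* Device TSI from spatially-resolved spectroscopy is not reconstructible
  from concentration changes alone; when it must be derived, the two-pool
  formula is an approximation.
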