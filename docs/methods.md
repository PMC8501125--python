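# Methods

This note documents the models implemented in `gaitsteps`, the defaults and
their rationale, the numerical choices, and what the synthetic-data tests do
and do not establish about real recordings.

## Signal model and step detection

The raw input is a uniformly sampled triaxial acceleration series in g
(nominally ±8 g range at 100 Hz; out-of-range samples warn rather than
error, since clipping is a sensor property, not a data error). All detection
operates on the **gravity-inclusive resultant** `r_i = √(ax² + ay² + az²)`:
no gravity removal and no band-pass filtering are applied. A still sensor
therefore reads ≈1 g on the resultant and every threshold is interpreted on
that scale. This is a deliberate design choice — high-pass filtering would
shift the excursion baseline and change the meaning of all five thresholds —
and its cost is that detector parameters are tied to the 1 g baseline.

A candidate step is a maximal run of samples with `r > θ_I` (an
*excursion*). Per excursion we record:

* `amplitude` — the maximum resultant (first sample wins argmax ties);
* `rise_time` / `decline_time` — threshold crossing to peak and peak to
  crossing, from sample timestamps;
* `slope` — `(amplitude − θ_I) / rise_time`, i.e. the mean rising slope
  above the baseline threshold. When the peak is the first excursion sample
  (`rise_time = 0`) the rise is taken over one sample period. This is one
  concrete reading of "the slope of the peak"; it is isolated in a single
  function so an alternative (e.g. maximum pointwise derivative) is a
  one-line change.
* `area` — trapezoidal integral of `r − θ_I` across the excursion (the
  "exceeding area" above the baseline). A single-sample excursion has zero
  trapezoidal area, which the default `θ_IV = 0` grids treat as passing.

Gates II–IV are `≥`-comparisons against their thresholds. Gate V is
**sequential**: the gap is measured to the previous *accepted* peak, must
lie within `[θ_V_min, θ_V_max]`, and the first accepted peak is exempt.
`θ_V_min` (default 0.2 s) is a refractory bound against double-counting
heel-strike ringing; `θ_V_max` encodes that consecutive steps are close in
time. There is no "restart" after a long gap: a walker who pauses longer
than `θ_V_max` contributes no further accepted steps until the detector is
re-run on a new span. This is the literal reading of the rule as specified;
for free-living data a segmented (per-bout) invocation is the intended
usage pattern.

### Monotonicity caveat

Tightening any of the minimum gates (θ_I–θ_IV) cannot increase the count
*when gate V is non-binding*: each gate is then a per-candidate filter and
the ordering is a theorem. With gate V binding the sequential chain can
re-route — removing one accepted peak changes the gap reference of its
successors — and counts are not globally monotone in any single threshold
(nor, by a symmetric cascade through the refractory bound, exactly monotone
in `θ_V_max` on adversarial signals). On gait-like signals with regular
inter-step gaps the orderings hold empirically; the test suite asserts
exactly these two regimes.

## Threshold optimization

"Training" is an exhaustive scan of the Cartesian product of candidate
threshold lists. The objective is the unweighted mean of
`|detected − actual| / actual` over every (recording, segment) pair;
per-speed weighting is possible by constructing training examples per
speed. The argmin is returned with ties broken by the earliest point in
lexicographic scan order over
(θ_I, θ_II, θ_III, θ_IV, θ_V_min, θ_V_max), and the full score table is
returned for audit. There is no randomness anywhere in the optimizer.

Default grids (package defaults, not values from any study; all
config-overridable): θ_I ∈ 1.05–1.6 g step 0.05; θ_II ∈ 1.1–2.5 g step 0.1;
θ_III ∈ 0–20 g/s step 2; θ_IV ∈ 0–0.4 g·s step 0.05; θ_V_max ∈ 0.6–2.0 s
step 0.2; θ_V_min fixed at 0.2 s. These bracket human cadence (roughly
0.5–3 Hz step frequency) and waist-sensor peak amplitudes from shuffle to
run. The grids deliberately allow `θ_II < θ_I`; such points are valid but
the amplitude gate is then vacuous (every excursion already exceeds θ_I),
so they score identically to `θ_II = θ_I`. Excursion features depend only
on θ_I, so the implementation extracts features once per (recording, θ_I)
and sweeps the remaining five axes in a compiled kernel; the pure-Python
path and the kernel are asserted equal in the tests.

## Energy expenditure

**Accelerometer chain.** The resultant is cut into non-overlapping epochs
(default 6 s — the epoch length customary in the MAD literature; the right
value for a specific device should be calibrated) and each epoch's mean
amplitude deviation `MAD = (1/N) Σ |r_i − R̄|` is expressed in mg. Oxygen
uptake follows the affine regression `VO₂ = 7.920 + 0.0331·MAD`
(ml·kg⁻¹·min⁻¹), and MET = VO₂/3.5. The source prints the regression with
a typographically ambiguous dash; the literal minus would make VO₂ *fall*
with rising activity, contradicting the monotone MAD–intensity relationship
the regression's lineage establishes, so "+" is the default and the literal
"−" is available (`sign="minus"` / `--literal-ee-sign`). Both readings are
unit-tested.

**Comparator equations.** ActiGraph adult cut-points:
`MET = 1.439008 + 0.000795·CPM` (counts per minute are an input here — the
proprietary count generation is not re-derived). activPAL:
`MET·h = 1.4·d + K·(c/120)·d` with cadence `c` (steps/min) and duration `d`
(h). The printed constant "(4–14)" read literally gives negative energy;
the default uses `K = 4 − 1.4 = 2.6` (the published constant pattern), the
literal `K = −10` sits behind `convention="literal"`.

**Indirect-calorimetry reference.** Weir:
`kcal/day = 1.44·(3.94·VO₂ + 1.11·VCO₂)` with VO₂/VCO₂ in **ml/min**
(documented unit contract; a resting adult is ~250 ml/min — L/min inputs
would be three orders of magnitude off). Resting metabolic rate is the Weir
rate of the mean gas exchange over the final five minutes of a supine
plateau, multiplied by 1.07 to correct for posture. Minutes with RER
outside [0.7, 0.99] are flagged, not rejected — the band is a plausibility
monitor, not an exclusion rule. Protocol totals sum per-minute Weir rates
divided by 1440 min/day.

## Agreement statistics

MAPE is the mean of per-pair `|A−F|/A × 100` with the sample sd of those
percentages; a mean above 5.0% is flagged as relevant disagreement. The
paired t test is classical (two-sided, 95% CI of the mean difference);
zero-variance differences return a flagged degenerate result with undefined
p rather than an error. ICC defaults to the two-way random-effects,
absolute-agreement, single-measure form ICC(2,1) — the standard model when
two methods should be interchangeable — computed from the two-way ANOVA
mean squares with the F test (MSR/MSE) and the McGraw–Wong 95% CI; the
consistency form ICC(3,1) is available. Negative ICC estimates are possible
in small samples and are reported as-is with category "low"; the bands are
>0.90 excellent, (0.75, 0.90] good, [0.60, 0.75] moderate, <0.60 low.
Bland–Altman reports the mean difference and mean ± 1.96 sd limits with the
per-pair (mean, difference) payload for plotting. R² is from the OLS fit of
estimated on actual. For cells with n < 3 (where ICC and regression are
inestimable) reports carry `None` in those fields rather than failing.

## Synthetic gait generator

The generator targets the detector's feature space, not human kinematics:
each step is a Gaussian bump (default full width 0.1 s) of speed-dependent
amplitude added to a 1 g baseline on the resultant, distributed across the
three axes by a fixed random per-subject unit orientation vector (so the
vector norm recovers the planted waveform exactly), plus per-axis Gaussian
noise. Step times advance by `60/cadence(t)` with per-step multiplicative
jitter; every planted peak time is recorded, giving exact per-segment
ground truth.

Defaults (chosen as plausible adult values; explicitly not measurements):
cadence 70/95/110/120/150/160 steps·min⁻¹ and amplitude
0.4/0.8/1.1/1.4/2.1/2.5 g above baseline at 1.5/3/4.5/6/9/10.5 km/h;
per-subject cadence jitter sd 5%, per-step gap jitter sd 3%, noise sd
0.05 g. Each stage begins with a 5–10 s ramp (uniformly drawn) during which
cadence and amplitude interpolate linearly from the previous stage (from
60%/50% of target on the first stage); ramp steps count toward their stage.
Cohorts draw per-subject seeds from a spawned `SeedSequence`, so a master
seed reproduces the cohort bit for bit.

What passing tests on this generator establish: the detection rule,
optimizer, energy chain and statistics are implemented correctly, and the
pipeline closes end-to-end (planted steps are recovered exactly on clean
data and within the 5% disagreement bound after optimization under noise).
What they do not establish: performance on real gait — the generator has no
double-support phases, no heel-strike ringing, no posture transitions, no
soft-tissue artefact, and its noise is white. Threshold values optimized on
synthetic cohorts are demonstrations of the optimizer, not device
calibrations.

## Problem sizes and numerics

The standard experiment simulates 10-subject cohorts over four 4-minute
stages (3–9 km/h) at 100 Hz (~96 000 samples per subject) and sweeps the
full default grid (142 560 points); this completes in well under a minute
on one CPU because feature extraction is O(N) per (recording, θ_I) and the
gate sweep is a compiled loop over precomputed feature arrays. Timestamps
must be uniform within 1 µs of the nominal period; non-uniform input is
rejected by default, with optional linear-interpolation resampling behind
an explicit flag. Epochs drop the trailing partial window. Floating-point
tie-breaks are deterministic (first argmax sample; earliest grid point in
scan order), so every run with a fixed seed and config is value-identical.
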