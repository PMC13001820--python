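# Methods

This note documents the models, parameter choices, and numerical decisions
behind `msreach`, and what the synthetic-data tests do and do not establish
about recorded data.

## Task model

A trial begins when the fixation target appears 20 cm above the hand start
position (`t_show_target = 0`).  After a uniformly drawn delay of 1.8–2.0 s
the target changes colour (go cue, `t_go`).  The go phase depends on the
condition:

- **cue monitoring** — nothing moves; the trial ends 0.3 + 0.8 s after the
  cue.
- **cursor tracking** — after the 0.3-s post-cue delay a cursor moves from
  start to target along a minimum-jerk profile with duration drawn from
  1.15–1.35 s; the trial ends when the cursor arrives.
- **reach visible** — the hand (with visible cursor) reaches to the target;
  the trial ends once the cursor has been inside the target disc for
  500 ms.
- **reach invisible** — the same reach without cursor feedback; the trial
  ends once hand speed has stayed below 10 cm/s for 200 ms.

The workspace geometry uses a 37-cm viewing distance, at which 1 cm on the
display subtends 1.5°.  All positions are expressed in cm, consistent with
how eye and hand signals are jointly analysed in this paradigm.

## Minimum-jerk kinematics

Point-to-point displacement follows the classic minimum-jerk polynomial

    y(t) = a (10τ³ − 15τ⁴ + 6τ⁵),  τ = t/d,

which has zero velocity and acceleration at both endpoints and peak speed
1.875·a/d at τ = ½.  Two closed-form corollaries are used as independent
oracles in the tests: the 5%-of-peak-speed criterion is first crossed at
τ* ≈ 0.0593 (root of 30τ²(1−τ)² = 0.09375), so a measured movement onset
lags the true onset by ≈ 0.059·d; and the 25%/75% distance marks are
crossed at τ ≈ 0.359/0.641, giving a mid-range average speed of
0.5·a/(0.283·d) (≈ 28.3 cm/s for a 20-cm, 1.25-s movement; the task's
speed-feedback target of 20 cm/s corresponds to slower movements).

The tracking cursor's lateral bow is not constrained beyond its endpoints
and 0.25-cm midpoint maximum; a half-sine x(t) = ±0.25·sin(πt/d) cm is used
— smooth, zero at both endpoints, extremal exactly once at the midpoint.
The bow direction is a fair coin per trial.

## Gaze simulator

Gaze is generated at 500 Hz around the target centre as the sum of

- a zero-mean random-walk drift with per-sample step SD 0.002 cm
  (≈ 1 cm/s ≈ 1.5°/s RMS inter-sample velocity before filtering), radially
  clamped at 1 cm from the target centre;
- white measurement noise with SD 0.01 cm (≈ 0.015°, typical of video
  eye tracking);
- injected microsaccades: smooth minimum-jerk displacement steps whose
  onsets are drawn from an inhomogeneous Poisson process by thinning.
  Amplitudes (clipped normal, mean 0.95 cm, SD 0.25) and durations (mean
  86 ms, SD 15 ms) follow the group means reported for this paradigm; the
  minimum-jerk step gives each event a main-sequence peak velocity of
  1.875·amplitude/duration (≈ 21 cm/s for the mean event).  When the
  accumulated event displacement exceeds 0.5 cm, the next event is aimed
  back toward the target centre (with 20° angular jitter), which keeps
  simulated gaze inside the 6-cm fixation window and mimics the
  drift-correcting role of real microsaccades.

Colliding sampled onsets are shifted just past the previous offset rather
than dropped, so event counts remain Poisson (the count-statistics
invariant) while events never overlap; an event shifted past the window
end is dropped (rare at the simulated rates).

The default rate profile mirrors the inhibition time course observed in
this paradigm, using its reported zone means as levels: 1.26 Hz baseline,
linear ramp over the last second before the cue down to 0.20 Hz, a 0.11-Hz
dip at 0.10–0.25 s after the cue, and a 0.60-Hz rebound from 0.30 s on.
The same profile is used for all four conditions by default, so
condition-level ANOVAs on default simulations are null by construction;
condition differences can be simulated by passing different profiles.

Reaction times are shifted log-normal (shift 0.1 s) with medians 0.38 s
(cursor visible) and 0.45 s (invisible); reach durations are clipped
normal, mean 1.36 s, SD 0.08 s, clipped to [1.16, 1.56] s.  The upper clip
keeps the pre-peak sub-10-cm/s phase of the reach shorter than the 200-ms
invisible-end rule, which (as in the real task) is only meaningful once
the movement is under way.  Recorded traces extend 0.1 s past the
rule-defined trial end so end events are observable in the data.

### What the simulator does not emulate

Saccadic waveforms are idealised steps (no dynamic overshoot), drift has no
persistent direction, noise is white and Gaussian (no tracker-specific
coloured noise or pupil artefacts), blinks appear only as planted missing
runs, and there are no head movements or calibration drifts.  Passing tests
therefore establish correctness of the *analysis operations* under
controlled conditions (detection equivalence, unbiased rate recovery, exact
exclusion bookkeeping), not robustness against every artefact of real
recordings.

## Preprocessing

Gaze is linearly upsampled onto the 1000-Hz hand grid (exact for the
piecewise-linear invariants; original instants preserved).  Missing samples
are NaN + mask; upsampling never bridges a gap, and filtering refuses
series with gaps — such trials are routed to the missing-eye exclusion
rule.  Filters are forward–backward Butterworth (eye: order 2, 15 Hz; hand:
order 3, 10 Hz), giving zero phase and a squared one-pass magnitude
response, with reflective padding of up to 1 s.  Derivatives are central
differences on the filtered positions, one-sided at the ends.

## Detection

The detection velocity is a 5-sample moving-window central difference
(v[i] ∝ x[i+2]+x[i+1]−x[i−1]−x[i−2]), the convention of velocity-threshold
saccade detection.  Thresholds are per-axis η = λσ with the median-based
SD σ = √(median(v²) − median(v)²) and λ = 5; a sample is saccadic iff it
lies strictly outside the ellipse (vx/ηx)² + (vy/ηy)² > 1.  Candidate
events are maximal suprathreshold runs of at least 40 samples (40 ms at
1000 Hz, a count-based criterion: the onset→offset span of a 40-sample run
is 39 ms).  Thresholds are estimated per trial over the target-on →
trial-end window, the same window to which detection is restricted.  No
amplitude ceiling is applied at detection — the 6-cm landing rule lives in
the exclusion stage — and events separated by short gaps are not merged.

Note that the zero-phase 15-Hz filter spreads a saccade's velocity pulse
symmetrically, so detected onsets precede injected onsets by ~10 ms in
full-pipeline simulations; detector-level onset accuracy (±5 ms) is tested
on unfiltered traces.

## Segmentation and exclusion

Movement onset is the last upward crossing of 5% of peak speed before the
speed peak at which acceleration is also ≥ 5% of the pre-peak acceleration
maximum; offset mirrors this after the peak with the deceleration maximum.
Reaction time is onset − go-cue; it therefore exceeds the true motor onset
by the criterion lag ≈ 0.059·d, which is why the simulator plants RT-rule
violations with a true RT of zero.

The four exclusion rules are applied sequentially and each trial is counted
under the first rule it violates, so per-rule counts sum to the total.
Fixation start is the first sample within 6 cm of the target after target
onset, fixation end the last such sample before the analysis window ends;
the window ends at the measured cursor-arrival time for reaches, the
scheduled cursor arrival for tracking, and the fixed 0.3 + 0.8-s endpoint
for cue monitoring.  Saccade "landing" distances are gaze positions at
detected event offsets.

## Rate estimation

Both estimators work on a 1-ms grid aligned to the go cue, with per-time
normalisation by the number of trials whose window covers that time.  The
state-based estimate divides the trial-averaged binary microsaccade state
by the mean event duration (by default the dataset's own mean detected
duration, making the estimator self-consistent: detected durations are
shorter than true durations, but the same convention is used in numerator
and denominator).  The causal-kernel estimate convolves per-millisecond
onset counts with ω(τ) = α²τe^(−ατ); α defaults to 1/0.050 s⁻¹ (kernel
peak 50 ms after an onset, mean lag 100 ms), and the discretised kernel is
renormalised to exact unit mass so an isolated onset contributes exactly
one event to the integrated rate.  The causal kernel delays rate mass by
~2/α, which slightly lowers its time-averaged estimate near window edges
relative to the state method (~2% on stationary simulations, well inside
the 10% agreement contract).

The movement zone is summarised per participant×condition as total onsets
within movement phases divided by total phase duration (kinematic
onset–offset for reaches, the scheduled interval for the other
conditions).  The two printed pre-cue windows (0.25-s analysis zone,
0.1-s inhibition zone) are kept as distinct named zones.

## Statistics

Within-subject ANOVAs are computed via pingouin (cross-checked against
statsmodels' AnovaRM in the tests); the uncorrected F is reported, with a
Greenhouse–Geisser p available.  A zero-variance table yields F = 0, p = 1
rather than 0/0.  Post hoc analysis uses pairwise paired t-tests with Holm
correction by default ("none" available — the underlying paradigm's
correction convention is not standardised, so numeric post hoc agreement
with any particular report should not be expected).  Letter groupings are
the maximal cliques of the non-significance graph, lettered in descending
order of clique mean.  Report-level ANOVAs are skipped when fewer than
three participants are present.

## Problem sizes used in the tests

Detector–oracle equivalence uses 100 random traces of up to 5 s; event
recovery 200 simulated trials; rate-method agreement 400 stationary trials;
zone-ordering recovery 100 replicates at the study scale of 4,080 sampled
event trains (17 participants × 60 trials × 4 conditions); ANOVA type-I
calibration 1,000 simulated 17-participant datasets drawn at the
zone-summary level (Poisson event counts over 60 trials in the 0.1-s-wide
initial-fixation zone with a shared per-participant baseline); exclusion
bookkeeping a 160-trial dataset with planted violations.  The README's
worked example uses 6 participants × 20 trials per condition.

## Known limitations

- Detected onset/offset times inherit the zero-phase filter's symmetric
  smearing; amplitudes and rates are unaffected, but absolute event timing
  from full-pipeline data carries a ~10-ms early bias.
- The state-based estimator treats overlapping events as a single state;
  the kernel estimator counts onsets — with merged detections the two can
  diverge at very high rates.
- The exclusion stage assumes segmentation ran first for reach trials
  (pipeline-order error otherwise); it does not re-derive kinematics.
- Post hoc p-values depend on the chosen correction; only the structure of
  the analysis, not any particular p-value, is a contract.
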