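# Methods

This note documents the models and procedures `taptiming` implements,
the synthetic-data generator's assumptions and calibration, and the
numerical choices that affect results.

## The paradigm and its representation

A session is 20 trials (10 per tapping mode). Each trial has 27 cycles
at a 1000 ms inter-beat interval: 15 pacing cycles with a 20 ms, 1 kHz
metronome tone, then 12 continuation cycles without it; trials are
separated by 20 s rests. Cycle indexing is 0-based with cycle *i*'s
nominal beat at *i·T* from trial onset, so the continuation phase
begins at 15 s on trend plots. Raw tap timestamps carry a constant
25 ms device-registration latency, subtracted before any analysis. All
times are milliseconds internally; trend plots and turning points use
seconds.

Two orderings of the 20 trials define the between-participant factor:
blocked (10 trials of one mode, then 10 of the other) and alternating
(mode switches every trial). The starting mode is counterbalanced by
assigning it alternately by participant index — deterministic and
testable. Within-participant factors are mode (synchronized/syncopated)
and phase (pacing/continuation). The alternating-by-single-trial
reading of "alternating" is a choice; alternation in small sets would
be a one-line change in `trial_schedule`.

## Timing metrics

Asynchrony is `tap − target` uniformly. For syncopated tapping the
target is the inter-beat midpoint; published formulations sometimes
write the syncopation measure with the opposite orientation, but a
uniform `tap − target` keeps "negative = anticipation" interpretable
across modes, which is the property analyses rely on. Continuation
targets stay anchored to the nominal metronome grid (extrapolated
silent beats) rather than re-anchoring to the participant's last tap:
the drift of an internal timekeeper is then visible in the asynchrony
trend instead of being absorbed into a moving reference.

Tap-to-target matching pairs each tap with its nearest target within
±T/2, each target used at most once, closer tap winning; exact ties go
to the later target. IRIs are differences between taps in *consecutive*
cycles; a gap spanning a missed tap is excluded rather than producing a
doubled interval, and each interval is labelled with the phase of its
later cycle (the first unpaced interval belongs to continuation).
No pacing warm-up cycles are excluded; callers can drop leading cycles
before summarizing if desired.

## Synthetic sessions

No public tap-event corpus exists for this paradigm at this scale, so
the generator is the package's test bed. It is a two-level scheme
chosen to reproduce the field's robust phenomena with few parameters:

- **Pacing**: `tap_i = target_i + bias + N(0, σ_pace)` — anchored
  (phase-corrected) tapping. Negative `bias` produces negative mean
  asynchrony.
- **Continuation**: intervals `I_k = T + drift + N(0, σ_tk)`
  accumulated from the last paced tap — an open-loop internal
  timekeeper. Asynchrony variance therefore grows linearly with cycles
  since metronome offset (random-walk accumulation), and a positive
  `drift` tilts the trend upward from the transition on.
- **Alternating degradation**: a constant `switch_cost_bias` on trials
  following a mode switch, plus a linear anticipatory bias ramp in
  pacing beginning at `anticipatory_drift_onset` seconds. The ramp is a
  pacing effect: its displacement carries into continuation through the
  anchor tap but accrues no further. This makes the alternating trend's
  curvature peak before metronome offset — the early turning point —
  while the blocked trend turns only at the transition.
- **Imperfection**: taps are dropped with `miss_prob`; with
  `outlier_prob` a tap's deviation is scaled by `outlier_scale`,
  clipped to ±0.45·T so gross errors stay within their own cycle (tap
  order and cycle identity remain intact; the IQR filter is what should
  remove them, not the matcher).

Defaults (the conditions every test and the acceptance script run
under): bias −34 ms and σ_pace 40 ms (pacing means near −34 ms with
realistic per-tap jitter), σ_tk 25 ms, drift +8 ms/cycle (≈ +50 ms mean
pacing→continuation increase), switch cost +25 ms, ramp onset 10 s at
5 ms/s for the alternating group only, miss 0.8 % and outlier 2 % with
scale 8 (a few removed observations per condition cell). Participants
draw sub-generators from `SeedSequence(seed, spawn_key=(index,))`, so
cohorts are bit-reproducible and extending a cohort never reshuffles
earlier participants. Optional per-participant bias heterogeneity
(`participant_bias_sd`) is off by default — the real distribution of
inter-subject variability is unknown and nothing here claims fidelity
to it.

What the generator does *not* emulate: learning or fatigue across
trials, musicianship/handedness effects, serial correlation of pacing
jitter (error correction is memoryless here), or tempo-dependent
variability. Passing tests therefore demonstrate that the estimators
recover what this generative model plants, not that the model captures
every property of human tapping.

Parameter sets whose deterministic (noise-free) deviation would reach
T/2 anywhere in a trial are rejected outright, since nearest-target
cycle assignment would become ambiguous.

## Preprocessing

Outliers are removed per condition cell (participant × design × mode ×
phase) with Tukey fences, k = 1.5, quartiles by linear interpolation
between order statistics. The "1.5 × IQR" rule is implemented as the
standard fences `[Q1 − k·IQR, Q3 + k·IQR]`; comparing raw values to
1.5·IQR itself would be scale-broken for signed asynchronies. Cells
with fewer than 4 values pass through untouched with a warning.
Balancing resamples every trial-phase block to exactly m = 5 values,
with replacement (a bootstrap), seeded and recorded. Balancing precedes
the regression observation unit (trial-phase means), so condition cells
contribute equally regardless of misses and rejections.

## Regression

The observation unit for the mode/phase/design regression is the
trial-phase mean of the index after preprocessing. Factors are
dummy-coded with references synchronized/pacing/blocked; all two-way
interactions are included by default (exposed in config). Per-factor
tests are full-versus-dropped-term F tests with partial
η² = SS_effect/(SS_effect + SS_error). Degrees of freedom are computed
from the actual design matrix; published df from comparable analyses
are not targets of this implementation. Tukey HSD uses the studentized
range with the Tukey–Kramer correction for unequal cells; with two
groups it reduces exactly to the pooled t test (q = t·√2). Post-hoc
power for the overall F test uses the noncentral F distribution with
λ = f²·n, df₁ = k, df₂ = n − k − 1; published power figures from
black-box software are not oracles — the noncentral-F contract is the
specification, and a Monte-Carlo simulation of regression F tests
verifies it.

## Growth curve and turning points

Cycle trends average within participant first, then across participants
(equal participant weighting), per design (optionally per design ×
mode). The trend model is a cubic smoothing spline; the penalty is
selected by generalized cross-validation by default because pure
interpolation of a noisy 27-point series makes the second derivative
oscillate uselessly. Setting `smoothing=0` gives exact interpolation; a
positive float fixes the penalty.

Turning points are the *signed* local maxima of the spline's second
derivative on a 0.1 s grid — upward curvature, trend acceleration — not
maxima of |curvature|; where a trend decelerates this choice matters
and is deliberate. Maxima below 50 % of the global maximum are
suppressed (threshold exposed), maxima within 1.5 grid steps of a
stronger one are merged, and a near-constant second derivative (e.g. a
purely quadratic trend) yields an explicit no-turning-point state. No
confidence intervals are attached to turning-point times; formal
changepoint inference is out of scope.

One structural subtlety: with drift starting at the first unpaced
interval, the cycle-mean trend's kink sits between the last paced cycle
(14 s) and the first continuation cycle (15 s), so estimates
concentrate on 14–15 s; the estimator is accurate to within one cycle
of the transition, which is also the resolution the cycle grid
supports.

## Difference-in-differences

Phase is the time dimension (pacing = 0, continuation = 1), design the
group (blocked = 0 control, alternating = 1 manipulated). The canonical
coding — intercept, time, group, time × group — is fitted by OLS; on a
balanced design the coefficients equal the cell-mean identities and β₃
is exactly the difference of differences. Report rows follow the
field's labelling convention ("Block" = control-group time change,
"Alternating" = group term, "Block × Alternating" = interaction); the
mapping is stated in the report header. Residual skewness and Pearson
(non-excess) kurtosis are reported as shape diagnostics. Tapping mode
is excluded as a covariate (it is randomized over trials within
participants). Standard errors are conventional OLS; trial-level
observations within a participant are not independent, so these SEs
are anti-conservative — clustered or bootstrap SEs are a documented
future option, not implemented. Parallel trends is an identifying
assumption, not a tested hypothesis.

## Problem sizes and reproducibility

Default analyses run on cohorts of 10 blocked + 13 alternating
participants (23 sessions, ≈ 12 000 tap events), the scale the
paradigm is designed around; estimator-recovery checks use 10–30
simulated cohorts of 6–10 participants each, enough for median
turning-point error below one cycle and 3-SE coverage of planted
effects. Every random draw flows from an explicit seed; a pipeline
run's outputs are byte-reproducible given config + seed, and each
artifact records the config snapshot's content hash.
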