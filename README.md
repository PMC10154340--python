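# taptiming

Simulation and analysis of **pacing–continuation finger-tapping**
experiments — the workhorse paradigm of sensorimotor-synchronization
research. Participants tap to a 1 Hz auditory metronome (*pacing*) and
keep tapping after it stops (*continuation*), either **synchronized**
(on the beat) or **syncopated** (between beats), with trials of the two
modes ordered **blocked** (all of one mode, then the other) or
**alternating** (mode switches every trial). The package is for
researchers who want to analyze such tap-event data — or prototype
analyses on realistic synthetic sessions — with the full statistical
pipeline: timing metrics, outlier handling, regression, trend
changepoints, and a causal estimate of the design effect.

## What it computes

Two per-cycle performance measures, with the convention that negative
means anticipation:

- **Asynchrony** `a_i = tap_i − target_i`, where the target is the beat
  `iT` (synchronized) or the inter-beat midpoint `(i + ½)T`
  (syncopated, "virtual" asynchrony); during continuation the targets
  are extrapolated silent beats on the same grid.
- **Inter-response interval** `IRI_i = tap_{i+1} − tap_i` between taps
  of consecutive cycles.

Around these sit four analysis stages:

1. **Preprocessing** — Tukey-fence outlier removal within condition
   cells (`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`) and bootstrap balancing to a
   constant per-cell sample size (m = 5).
2. **Regression** (`TimingRegression`) — OLS of the trial-phase mean
   index on dummy-coded mode, phase and design with two-way
   interactions; per-factor F tests with partial η²; Tukey HSD pairwise
   contrasts; noncentral-F post-hoc power for the overall model.
3. **Growth curve** (`GrowthCurveModel`) — a cubic smoothing spline
   (GCV-selected penalty) through the cycle-averaged trend; the signed
   maxima of its second derivative are the trend's **turning points**,
   e.g. the response to the metronome stopping at 15 s.
4. **Causal inference** (`DifferenceInDifferences`) — with phase as
   time (pacing = pre, continuation = post) and the blocked group as
   control, `Y = β₀ + β₁P + β₂G + β₃(P×G) + ε`; under parallel trends
   β₃ is the causal effect of the alternating design on the index.

Because raw tap data from such studies are rarely public, a seeded
generator produces sessions with the field's known phenomenology:
negative mean asynchrony in pacing, random-walk variance growth and
drift in continuation, switch costs and anticipatory degradation under
the alternating design, plus realistic miss/outlier rates.

## Worked example

```python
import taptiming as tt
from taptiming.preprocess import iqr_filter_frame

sessions = tt.simulate_cohort(10, 13, seed=1)      # 10 blocked, 13 alternating
events = tt.sessions_to_frame(sessions)
asyn = tt.asynchrony_frame(events)
kept, removed, report = iqr_filter_frame(asyn, "asynchrony_ms")
print(tt.summarize(kept, "asynchrony_ms"))
```

```
     design         mode        phase    n  mean_ms  sd_ms
alternating synchronized continuation 1502    56.92  78.57
alternating synchronized       pacing 1889    -7.70  39.28
alternating   syncopated continuation 1498    67.52  67.91
alternating   syncopated       pacing 1887    -5.39  40.45
    blocked synchronized continuation 1166    13.04  73.48
    blocked synchronized       pacing 1460   -33.38  39.78
    blocked   syncopated continuation 1165    33.37  70.75
    blocked   syncopated       pacing 1445   -35.06  37.94
```

Blocked-design pacing shows the classic negative mean asynchrony
(≈ −34 ms: taps anticipate the beat), continuation is slower and more
variable, and the alternating design degrades both phases. The design
effect and the trend changepoints:

```python
obs = tt.trial_phase_means(kept, "asynchrony_ms")
print(tt.DifferenceInDifferences(obs, "asynchrony_ms").fit().summary())
for series in tt.cycle_average(kept, "asynchrony_ms", grouping=["design"]):
    print(tt.GrowthCurveModel(series).fit().summary())
```

```
Difference-in-differences (OLS)
  outcome: asynchrony_ms, n = 920, R^2 = 0.4238
  ...
  Constant                  -34.270     3.001   -11.419
  Block                      57.603     4.244    13.572
  Alternating                27.689     3.992     6.936
  Block x Alternating        11.829     5.646     2.095

Growth-curve model (design=alternating)
  turning points: 10.0 s, 2.0 s, 12.0 s, 5.0 s (primary 10.0 s)
Growth-curve model (design=blocked)
  turning points: 14.0 s (primary 14.0 s)
```

The interaction row (β₃ ≈ +11.8 ms, t ≈ 2.1) is the estimated causal
effect of alternating trials on asynchrony growth from pacing to
continuation. The blocked trend turns once, at the pacing→continuation
transition; the alternating trend turns early (≈ 10 s), while the
metronome is still sounding — the anticipatory degradation the
alternating preset emulates.

The same pipeline runs from the shell:

```sh
taptiming simulate --n-block 10 --n-alt 13 --seed 1 --out sessions.csv
taptiming analyze --seed 1 --out bundle/
taptiming report bundle/
```

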