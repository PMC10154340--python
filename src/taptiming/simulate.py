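"""Synthetic tap-event generator for the pacing-continuation paradigm.

The study's raw data are request-only, so a generative stand-in provides
sessions with the statistical structure the analysis assumes.  The scheme
is two-level:

* **Pacing** taps are anchored to their targets with a constant bias
  (negative values emulate the negative mean asynchrony of paced tapping)
  plus independent Gaussian jitter.  Trials that follow a mode switch can
  carry an extra switch-cost bias, and a linear anticipatory bias ramp can
  start before metronome offset -- both emulate the degradation seen under
  an alternating trial ordering.
* **Continuation** taps accumulate intervals ``I_k = T + drift +
  N(0, timekeeper_sd)`` from the last paced tap, i.e. an internal-timekeeper
  random walk whose variance grows with cycle index.

Misses and gross-error taps are injected at small rates so downstream
outlier filtering and missing-data accounting have realistic work to do.
All randomness flows from a single master seed through per-participant
``SeedSequence`` spawn keys, so adding participants never reshuffles
earlier ones and output is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace as dc_replace

import numpy as np
import pandas as pd

from .design import (
    DesignKind,
    Mode,
    ModeOrder,
    Phase,
    TaskDesign,
    build_default_design,
    mode_order_for_participant,
    trial_schedule,
)

__all__ = [
    "GeneratorParams",
    "TapEvent",
    "Trial",
    "Session",
    "block_design_params",
    "alternating_design_params",
    "make_metronome",
    "target_time",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "sessions_to_frame",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the tap generator.

    Parameters
    ----------
    pacing_bias : float
        Mean pacing asynchrony in ms; negative emulates anticipation
        (negative mean asynchrony).
    pacing_sd : float
        SD of the per-tap Gaussian jitter during pacing, ms.
    continuation_timekeeper_sd : float
        Per-interval SD of the internal timekeeper during continuation, ms.
    continuation_drift : float
        Systematic interval lengthening (+) or shortening (-) per
        continuation cycle, ms.
    anticipatory_drift_onset : float or None
        Trial time in seconds at which the pacing bias starts ramping;
        ``None`` disables the ramp.  Used to emulate the early trend
        degradation of the alternating design.
    anticipatory_drift_rate : float
        Slope of that ramp, ms of extra bias per second past the onset.
    switch_cost_bias : float
        Extra bias (ms) on trials whose predecessor used the other mode.
    miss_prob : float
        Probability that a tap goes unregistered.
    outlier_prob : float
        Probability that a tap's deviation from target is multiplied by
        ``outlier_scale`` (a gross registration error).
    outlier_scale : float
        Multiplier applied to outlier deviations.
    participant_bias_sd : float
        SD of an optional per-participant random shift of ``pacing_bias``
        (inter-subject heterogeneity); 0 disables it.
    """

    pacing_bias: float = -34.0
    pacing_sd: float = 40.0
    continuation_timekeeper_sd: float = 25.0
    continuation_drift: float = 8.0
    anticipatory_drift_onset: float | None = None
    anticipatory_drift_rate: float = 5.0
    switch_cost_bias: float = 0.0
    miss_prob: float = 0.008
    outlier_prob: float = 0.02
    outlier_scale: float = 8.0
    participant_bias_sd: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pacing_sd", "continuation_timekeeper_sd", "participant_bias_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("miss_prob", "outlier_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def replace(self, **changes) -> "GeneratorParams":
        return dc_replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)


def block_design_params(**overrides) -> GeneratorParams:
    """Generator preset for the blocked trial ordering (stable pacing,
    drifting continuation; no switch costs)."""
    return GeneratorParams(**overrides)


def alternating_design_params(**overrides) -> GeneratorParams:
    """Generator preset for the alternating trial ordering: switch-cost
    bias on every post-switch trial and an anticipatory bias ramp starting
    before metronome offset."""
    defaults = dict(switch_cost_bias=25.0, anticipatory_drift_onset=10.0)
    defaults.update(overrides)
    return GeneratorParams(**defaults)


@dataclass(frozen=True)
class TapEvent:
    """One registered tap with its nominal target.

    ``tap_time = raw_tap_time - device_delay``; ``target_time`` is the
    beat (synchronized) or inter-beat midpoint (syncopated), extrapolated
    on the nominal grid during continuation.
    """

    participant_id: str
    trial_index: int
    cycle_index: int
    mode: Mode
    phase: Phase
    raw_tap_time: float
    tap_time: float
    target_time: float

    @property
    def asynchrony(self) -> float:
        return self.tap_time - self.target_time


@dataclass
class Trial:
    trial_index: int
    mode: Mode
    events: list[TapEvent]
    beats: np.ndarray  # metronome onsets, pacing phase only


@dataclass
class Session:
    participant_id: str
    design_kind: DesignKind
    mode_order: ModeOrder
    trials: list[Trial]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": ev.participant_id,
                "design": self.design_kind.value,
                "mode": ev.mode.value,
                "phase": ev.phase.value,
                "trial": ev.trial_index,
                "cycle": ev.cycle_index,
                "raw_tap_ms": ev.raw_tap_time,
                "tap_ms": ev.tap_time,
                "target_ms": ev.target_time,
            }
            for trial in self.trials
            for ev in trial.events
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id", "design", "mode", "phase", "trial",
                "cycle", "raw_tap_ms", "tap_ms", "target_ms",
            ],
        )


def make_metronome(design: TaskDesign) -> np.ndarray:
    """Metronome onset times for one trial: ``0, T, 2T, ...`` over the
    pacing cycles only (no beats during continuation)."""
    return np.arange(design.pacing_cycles, dtype=float) * design.inter_beat_interval


def target_time(design: TaskDesign, mode: Mode, cycle: int) -> float:
    """Nominal target for 0-based ``cycle``: the beat ``i*T`` for
    synchronized tapping, the midpoint ``(i + 1/2)*T`` for syncopated;
    extrapolated on the same grid past metronome offset."""
    t = cycle * design.inter_beat_interval
    if mode is Mode.SYNCOPATED:
        t += design.inter_beat_interval / 2.0
    return t


def _max_expected_deviation(design: TaskDesign, params: GeneratorParams) -> float:
    """Largest |expected tap deviation| over a trial, noise excluded."""
    ramp = 0.0
    if params.anticipatory_drift_onset is not None:
        trial_end_s = design.total_cycles * design.inter_beat_interval / 1000.0
        ramp = abs(params.anticipatory_drift_rate) * max(
            0.0, trial_end_s - params.anticipatory_drift_onset
        )
    pacing = abs(params.pacing_bias) + abs(params.switch_cost_bias) + ramp
    continuation = (
        abs(params.pacing_bias)
        + abs(params.switch_cost_bias)
        + ramp
        + abs(params.continuation_drift) * design.continuation_cycles
    )
    return max(pacing, continuation)


def simulate_trial(
    design: TaskDesign,
    params: GeneratorParams,
    mode: Mode,
    trial_index: int,
    rng: np.random.Generator,
    *,
    participant_id: str = "P00",
    after_switch: bool = False,
    bias_offset: float = 0.0,
) -> list[TapEvent]:
    """Simulate the registered taps of one trial.

    Pacing taps are drawn around their targets; continuation taps
    accumulate timekeeper intervals from the last paced tap.  Events are
    dropped with ``miss_prob`` and corrupted with ``outlier_prob``.
    ``bias_offset`` shifts the pacing bias (per-participant heterogeneity).

    Raises
    ------
    ValueError
        If the expected (noise-free) deviation anywhere in the trial
        exceeds T/2, which would break nearest-target cycle assignment.
    """
    T = design.inter_beat_interval
    if _max_expected_deviation(design, params) + abs(bias_offset) >= T / 2.0:
        raise ValueError(
            "expected tap deviation exceeds half the inter-beat interval; "
            "cycle assignment would be ambiguous"
        )

    bias = params.pacing_bias + bias_offset
    if after_switch:
        bias += params.switch_cost_bias

    def ramp(t_ms: float) -> float:
        if params.anticipatory_drift_onset is None:
            return 0.0
        excess_s = t_ms / 1000.0 - params.anticipatory_drift_onset
        return params.anticipatory_drift_rate * max(0.0, excess_s)

    tap_times = np.empty(design.total_cycles)
    # pacing: anchored Gaussian jitter around each target
    for i in range(design.pacing_cycles):
        tgt = target_time(design, mode, i)
        noise = rng.normal(0.0, params.pacing_sd) if params.pacing_sd > 0 else 0.0
        tap_times[i] = tgt + bias + ramp(tgt) + noise
    # continuation: interval accumulation from the last paced tap; the
    # anticipatory ramp is a pacing effect, so its displacement carries
    # over through the anchor tap but accrues no further
    t = tap_times[design.pacing_cycles - 1]
    for i in range(design.pacing_cycles, design.total_cycles):
        sd = params.continuation_timekeeper_sd
        noise = rng.normal(0.0, sd) if sd > 0 else 0.0
        t = t + T + params.continuation_drift + noise
        tap_times[i] = t

    events: list[TapEvent] = []
    for i in range(design.total_cycles):
        if params.miss_prob > 0 and rng.random() < params.miss_prob:
            continue
        tgt = target_time(design, mode, i)
        dev = tap_times[i] - tgt
        if params.outlier_prob > 0 and rng.random() < params.outlier_prob:
            # gross registration error, but still within its own cycle so
            # tap order and cycle identity stay intact
            dev = float(np.clip(dev * params.outlier_scale, -0.45 * T, 0.45 * T))
        tap = tgt + dev
        events.append(
            TapEvent(
                participant_id=participant_id,
                trial_index=trial_index,
                cycle_index=i,
                mode=mode,
                phase=design.phase_of_cycle(i),
                raw_tap_time=tap + design.device_delay,
                tap_time=tap,
                target_time=tgt,
            )
        )
    return events


def simulate_session(
    design: TaskDesign,
    params: GeneratorParams,
    *,
    participant_id: str,
    rng: np.random.Generator,
) -> Session:
    """Simulate a full session following the design's trial schedule."""
    bias_offset = (
        rng.normal(0.0, params.participant_bias_sd)
        if params.participant_bias_sd > 0
        else 0.0
    )
    schedule = trial_schedule(design)
    trials: list[Trial] = []
    prev_mode: Mode | None = None
    for trial_index, mode in schedule:
        after_switch = prev_mode is not None and prev_mode is not mode
        events = simulate_trial(
            design,
            params,
            mode,
            trial_index,
            rng,
            participant_id=participant_id,
            after_switch=after_switch,
            bias_offset=bias_offset,
        )
        trials.append(
            Trial(trial_index=trial_index, mode=mode, events=events,
                  beats=make_metronome(design))
        )
        prev_mode = mode
    return Session(
        participant_id=participant_id,
        design_kind=design.design_kind,
        mode_order=design.mode_order,
        trials=trials,
    )


def simulate_cohort(
    n_block: int,
    n_alternating: int,
    params_by_group: dict[DesignKind, GeneratorParams] | None = None,
    seed: int = 0,
    design: TaskDesign | None = None,
) -> list[Session]:
    """Simulate a cohort: ``n_block`` blocked-design and ``n_alternating``
    alternating-design participants.

    Participant ``j`` (global 0-based index, blocked group first) draws
    from ``SeedSequence(seed, spawn_key=(j,))``, so the output is
    deterministic in ``seed`` and earlier participants are unaffected by
    adding later ones.  Starting mode is counterbalanced by participant
    index within each group.
    """
    if n_block < 0 or n_alternating < 0 or n_block + n_alternating < 1:
        raise ValueError("need at least one participant")
    if params_by_group is None:
        params_by_group = {
            DesignKind.BLOCKED: block_design_params(),
            DesignKind.ALTERNATING: alternating_design_params(),
        }
    base = design if design is not None else build_default_design()

    sessions: list[Session] = []
    groups = [(DesignKind.BLOCKED, n_block, "B"), (DesignKind.ALTERNATING, n_alternating, "A")]
    global_index = 0
    for kind, count, prefix in groups:
        for k in range(count):
            ss = np.random.SeedSequence(seed, spawn_key=(global_index,))
            rng = np.random.default_rng(ss)
            d = base.replace(
                design_kind=kind,
                mode_order=mode_order_for_participant(k),
            )
            sessions.append(
                simulate_session(
                    d,
                    params_by_group[kind],
                    participant_id=f"{prefix}{k:02d}",
                    rng=rng,
                )
            )
            global_index += 1
    return sessions


def sessions_to_frame(sessions: list[Session]) -> pd.DataFrame:
    """Concatenate sessions into one tidy tap-event table."""
    frames = [s.to_frame() for s in sessions]
    return pd.concat(frames, ignore_index=True)
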