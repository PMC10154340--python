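"""Structure of the pacing-continuation finger-tapping paradigm.

A session consists of trials of rhythmic tapping to (and then without) a
1 Hz auditory metronome.  Each trial has a *pacing* phase (metronome on)
followed by a *continuation* phase (metronome off, the participant keeps
the rhythm from an internal timekeeper).  Tapping is performed in one of
two coordination modes: *synchronized* (tap on the beat) or *syncopated*
(tap midway between beats).  Trials of the two modes are ordered either
*blocked* (all of one mode, then all of the other) or *alternating*
(mode switches every trial) -- the between-participant design factor.

All times are in milliseconds internally; trend plots convert to seconds.
Cycle indexing is 0-based with cycle ``i``'s nominal beat at ``i * T``
from trial onset (trial onset = first beat = 0 ms).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict


class Mode(str, enum.Enum):
    """Tapping coordination mode."""

    SYNCHRONIZED = "synchronized"
    SYNCOPATED = "syncopated"

    def other(self) -> "Mode":
        return Mode.SYNCOPATED if self is Mode.SYNCHRONIZED else Mode.SYNCHRONIZED


class Phase(str, enum.Enum):
    """Maintenance phase within a trial."""

    PACING = "pacing"
    CONTINUATION = "continuation"


class DesignKind(str, enum.Enum):
    """Between-participant trial-ordering design."""

    BLOCKED = "blocked"
    ALTERNATING = "alternating"


class ModeOrder(str, enum.Enum):
    """Which tapping mode a participant starts with (counterbalancing)."""

    SYNC_FIRST = "sync_first"
    SYNCOPATION_FIRST = "syncopation_first"

    @property
    def first_mode(self) -> Mode:
        return Mode.SYNCHRONIZED if self is ModeOrder.SYNC_FIRST else Mode.SYNCOPATED


@dataclass(frozen=True)
class ConditionLabel:
    """One cell of the mode x phase x design analysis cross.

    Mode and phase are within-participant factors; design is the
    between-participant factor.  The 2 x 2 x 2 cross defines the eight
    analysis cells.
    """

    mode: Mode
    phase: Phase
    design: DesignKind


@dataclass(frozen=True)
class TaskDesign:
    """Timing constants and trial structure of the tapping task.

    Parameters
    ----------
    inter_beat_interval : float
        Metronome period T in ms (default 1000 ms, i.e. 1 Hz).
    tone_duration : float
        Duration of each metronome tone, ms.
    pacing_cycles, continuation_cycles : int
        Cycles per phase (default 15 + 12 = 27 per trial).
    trials_per_mode : int
        Trials of each tapping mode per participant (default 10, so 20
        trials per session).
    rest_duration : float
        Inter-trial rest, seconds.
    device_delay : float
        Constant registration latency of the tapping device, ms; raw tap
        times are corrected by subtracting it.
    design_kind : DesignKind
        Blocked or alternating trial ordering.
    mode_order : ModeOrder
        Which mode comes first.
    """

    inter_beat_interval: float = 1000.0
    tone_duration: float = 20.0
    pacing_cycles: int = 15
    continuation_cycles: int = 12
    trials_per_mode: int = 10
    rest_duration: float = 20.0
    device_delay: float = 25.0
    design_kind: DesignKind = DesignKind.BLOCKED
    mode_order: ModeOrder = ModeOrder.SYNC_FIRST

    def __post_init__(self) -> None:
        if self.inter_beat_interval <= 0:
            raise ValueError("inter_beat_interval must be positive")
        for name in ("pacing_cycles", "continuation_cycles", "trials_per_mode"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.device_delay < 0:
            raise ValueError("device_delay must be non-negative")

    @property
    def total_cycles(self) -> int:
        """Cycles per trial: pacing plus continuation."""
        return self.pacing_cycles + self.continuation_cycles

    @property
    def total_trials(self) -> int:
        return 2 * self.trials_per_mode

    @property
    def continuation_onset_ms(self) -> float:
        """Nominal time of the first continuation-phase beat, ms."""
        return self.pacing_cycles * self.inter_beat_interval

    def phase_of_cycle(self, cycle: int) -> Phase:
        """Phase of 0-based cycle ``cycle`` within a trial."""
        if not 0 <= cycle < self.total_cycles:
            raise ValueError(f"cycle {cycle} outside 0..{self.total_cycles - 1}")
        return Phase.PACING if cycle < self.pacing_cycles else Phase.CONTINUATION

    def replace(self, **changes) -> "TaskDesign":
        cfg = asdict(self)
        cfg.update(changes)
        return TaskDesign(**cfg)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["design_kind"] = self.design_kind.value
        d["mode_order"] = self.mode_order.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskDesign":
        d = dict(d)
        if "design_kind" in d:
            d["design_kind"] = DesignKind(d["design_kind"])
        if "mode_order" in d:
            d["mode_order"] = ModeOrder(d["mode_order"])
        return cls(**d)


def build_default_design(**overrides) -> TaskDesign:
    """The study's default task configuration.

    1 Hz metronome (T = 1000 ms), 20 ms tones, 15 pacing + 12 continuation
    cycles per trial, 10 trials per mode, 20 s inter-trial rest, 25 ms
    device-delay correction.
    """
    return TaskDesign(**overrides)


def trial_schedule(design: TaskDesign) -> list[tuple[int, Mode]]:
    """Ordered ``(trial_index, mode)`` schedule for a session.

    Blocked: all ``trials_per_mode`` trials of the first mode, then all of
    the other.  Alternating: modes alternate every trial.  The starting
    mode is set by ``design.mode_order``.
    """
    first = design.mode_order.first_mode
    second = first.other()
    if design.design_kind is DesignKind.BLOCKED:
        modes = [first] * design.trials_per_mode + [second] * design.trials_per_mode
    else:
        modes = [first if t % 2 == 0 else second for t in range(design.total_trials)]
    return list(enumerate(modes))


def mode_order_for_participant(index: int) -> ModeOrder:
    """Counterbalanced starting mode: even participant indices start with
    synchronization, odd with syncopation."""
    return ModeOrder.SYNC_FIRST if index % 2 == 0 else ModeOrder.SYNCOPATION_FIRST
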