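"""Timing performance measures: (virtual) asynchrony and inter-response
interval.

*Asynchrony* is the signed tap-minus-target difference for each cycle:
negative means the tap anticipated the target, positive that it lagged.
For synchronized tapping the target is the metronome beat ``i*T``; for
syncopated tapping it is the inter-beat midpoint ``(i + 1/2)*T`` ("virtual"
asynchrony).  During continuation both target sequences are extrapolated
on the same nominal grid past metronome offset, so the measure is defined
with or without the tone.  The sign convention is ``tap - target``
uniformly, so negative always means anticipation in both modes.

*Inter-response interval* (IRI) is the time between taps in consecutive
cycles, the fluency/tempo measure; gaps spanning a missed cycle are
excluded rather than producing a doubled interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import Mode, Phase, TaskDesign

__all__ = [
    "correct_device_delay",
    "target_times",
    "match_taps",
    "asynchrony",
    "asynchrony_frame",
    "iri",
    "iri_frame",
    "summarize",
]

CONDITION_COLS = ["design", "mode", "phase"]


def correct_device_delay(raw_tap_times, delay: float) -> np.ndarray:
    """Subtract the constant device registration latency from raw tap
    times (order preserved)."""
    if delay < 0:
        raise ValueError("delay must be non-negative")
    return np.asarray(raw_tap_times, dtype=float) - delay


def target_times(
    design: TaskDesign,
    mode: Mode,
    phase: Phase | None = None,
) -> np.ndarray:
    """Nominal target times for one trial.

    Synchronized targets are the beats ``i*T``; syncopated targets the
    midpoints ``(i + 1/2)*T``.  Continuation targets continue the same
    arithmetic sequence beyond the last real beat (extrapolated silent
    beats).  ``phase=None`` returns all cycles.
    """
    if phase is Phase.PACING:
        cycles = np.arange(design.pacing_cycles)
    elif phase is Phase.CONTINUATION:
        cycles = np.arange(design.pacing_cycles, design.total_cycles)
    else:
        cycles = np.arange(design.total_cycles)
    offset = design.inter_beat_interval / 2.0 if mode is Mode.SYNCOPATED else 0.0
    return cycles * design.inter_beat_interval + offset


@dataclass
class MatchResult:
    """Tap-to-target assignment: matched ``(tap, target)`` pairs plus
    counts of unmatched taps and targets."""

    pairs: list[tuple[float, float]]
    unmatched_taps: int
    missing_targets: int


def match_taps(tap_times, target_times, window: float) -> MatchResult:
    """Pair each tap with its nearest target within ``+/-window`` ms.

    Each target is used at most once; taps are assigned greedily in order
    of increasing |tap - target| so the closer of two competing taps wins.
    Exact ties break toward the later target.  Unpaired taps and targets
    are counted as flagged/missing.
    """
    taps = np.asarray(tap_times, dtype=float)
    targets = np.asarray(target_times, dtype=float)
    if targets.size > 1:
        min_gap = np.min(np.diff(np.sort(targets)))
        if window > min_gap / 2.0:
            raise ValueError("window must not exceed half the target spacing")

    # candidate (distance, tap index, target index), later target wins ties
    candidates = []
    for ti, tap in enumerate(taps):
        for gi, tgt in enumerate(targets):
            d = abs(tap - tgt)
            if d <= window:
                candidates.append((d, -tgt, ti, gi))
    candidates.sort()
    used_taps: set[int] = set()
    used_targets: set[int] = set()
    pairs: list[tuple[float, float]] = []
    for _, _, ti, gi in candidates:
        if ti in used_taps or gi in used_targets:
            continue
        used_taps.add(ti)
        used_targets.add(gi)
        pairs.append((taps[ti], targets[gi]))
    pairs.sort(key=lambda p: p[1])
    return MatchResult(
        pairs=pairs,
        unmatched_taps=len(taps) - len(used_taps),
        missing_targets=len(targets) - len(used_targets),
    )


def asynchrony(pairs) -> np.ndarray:
    """Signed asynchrony ``tap - target`` for matched pairs; negative =
    anticipation."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        return np.empty(0)
    return arr[:, 0] - arr[:, 1]


def asynchrony_frame(events: pd.DataFrame) -> pd.DataFrame:
    """Add a signed ``asynchrony_ms`` column to a tidy tap-event table."""
    out = events.copy()
    out["asynchrony_ms"] = out["tap_ms"] - out["target_ms"]
    return out


def iri(tap_times, cycles=None) -> np.ndarray:
    """Inter-response intervals ``tap_{i+1} - tap_i``.

    If ``cycles`` is given, only pairs in consecutive cycles contribute;
    gaps spanning a missed cycle are excluded.  Non-monotone tap times
    signal a corrupted session and raise.
    """
    taps = np.asarray(tap_times, dtype=float)
    if taps.size < 2:
        return np.empty(0)
    if np.any(np.diff(taps) <= 0):
        raise ValueError("tap times must be strictly increasing")
    diffs = np.diff(taps)
    if cycles is None:
        return diffs
    cyc = np.asarray(cycles)
    keep = np.diff(cyc) == 1
    return diffs[keep]


def iri_frame(events: pd.DataFrame) -> pd.DataFrame:
    """Per-trial IRI table from a tidy tap-event table.

    Within each participant x trial, intervals between consecutive-cycle
    taps are computed; each interval is labelled with the phase of its
    later cycle (the first unpaced tap's interval belongs to
    continuation).
    """
    rows = []
    for (pid, trial), g in events.groupby(["participant_id", "trial"], sort=True):
        g = g.sort_values("cycle")
        taps = g["tap_ms"].to_numpy()
        cyc = g["cycle"].to_numpy()
        if len(taps) < 2:
            continue
        vals = iri(taps, cyc)
        keep = np.diff(cyc) == 1
        later = g.iloc[1:][keep]
        for (_, row), v in zip(later.iterrows(), vals):
            rows.append(
                {
                    "participant_id": pid,
                    "design": row["design"],
                    "mode": row["mode"],
                    "phase": row["phase"],
                    "trial": trial,
                    "cycle": row["cycle"],
                    "iri_ms": v,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["participant_id", "design", "mode", "phase", "trial", "cycle", "iri_ms"],
    )


def summarize(
    df: pd.DataFrame,
    value_col: str,
    by: list[str] | None = None,
) -> pd.DataFrame:
    """Per-condition mean and SD table (columns: grouping, n, mean_ms,
    sd_ms).  Empty condition cells are simply absent from the table."""
    by = by or CONDITION_COLS
    g = df.groupby(by, sort=True)[value_col]
    out = g.agg(n="count", mean_ms="mean", sd_ms="std").reset_index()
    out["sd_ms"] = out["sd_ms"].fillna(0.0)
    return out
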