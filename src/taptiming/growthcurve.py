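"""Cubic-spline growth-curve modelling of cycle-averaged timing trends.

The per-cycle trend of a timing index (asynchrony or IRI averaged across
trials, then across participants) is modelled with a cubic spline -- a
smoothing spline with generalized cross-validated penalty by default,
pure interpolation when smoothing is 0.  The spline's second derivative
measures the local acceleration of the trend; its (signed) maxima mark
*turning points*, the times at which the behavioral trend changes regime,
e.g. at the pacing-to-continuation transition when the metronome stops.

Times are in seconds on the nominal cycle grid: 0-based cycle ``i`` of a
1 Hz task sits at ``i`` seconds, so with 15 pacing cycles the
continuation onset is 15 s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from .design import TaskDesign, build_default_design

__all__ = [
    "CycleSeries",
    "cycle_average",
    "fit_growth_spline",
    "turning_points",
    "TurningPointResult",
    "GrowthCurveModel",
    "GrowthCurveResults",
]


@dataclass
class CycleSeries:
    """A timing statistic averaged per cycle position.

    ``times`` are cycle positions in seconds (strictly increasing),
    ``values`` the cycle-averaged statistic in ms.  ``counts`` records how
    many participants contributed per cycle; ``label`` the grouping cell.
    """

    times: np.ndarray
    values: np.ndarray
    label: dict = field(default_factory=dict)
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equally long")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def dropna(self) -> "CycleSeries":
        keep = ~np.isnan(self.values)
        counts = self.counts[keep] if self.counts is not None else None
        return CycleSeries(self.times[keep], self.values[keep], dict(self.label), counts)


def cycle_average(
    df: pd.DataFrame,
    value_col: str,
    grouping: list[str] | None = None,
    design: TaskDesign | None = None,
) -> list[CycleSeries]:
    """Cycle-position trends: mean across trials within participant, then
    across participants, per grouping cell.

    ``df`` is a tidy table with ``participant_id``, ``cycle`` and the
    value column (e.g. from :func:`taptiming.metrics.asynchrony_frame`).
    Cycle positions convert to seconds via the design's inter-beat
    interval (default 1 s).  Cycles with no data are absent from the
    series.
    """
    grouping = grouping if grouping is not None else ["design"]
    design = design or build_default_design()
    scale = design.inter_beat_interval / 1000.0
    out: list[CycleSeries] = []
    group_iter = df.groupby(grouping, sort=True) if grouping else [((), df)]
    for key, g in group_iter:
        key = key if isinstance(key, tuple) else (key,)
        per_participant = (
            g.groupby(["participant_id", "cycle"], sort=True)[value_col].mean().reset_index()
        )
        grand = per_participant.groupby("cycle", sort=True)[value_col].agg(["mean", "count"])
        out.append(
            CycleSeries(
                times=grand.index.to_numpy(dtype=float) * scale,
                values=grand["mean"].to_numpy(),
                label=dict(zip(grouping, key)),
                counts=grand["count"].to_numpy(),
            )
        )
    return out


def fit_growth_spline(series: CycleSeries, smoothing: float | str = "gcv") -> BSpline:
    """Fit the cubic growth spline to a cycle series.

    ``smoothing="gcv"`` selects the penalty by generalized
    cross-validation; ``0`` interpolates exactly; a positive float is used
    as the penalty directly.  Needs at least 5 points.
    """
    s = series.dropna()
    if s.times.size < 5:
        raise ValueError(f"need >= 5 points to fit the growth spline, got {s.times.size}")
    if smoothing == "gcv":
        return make_smoothing_spline(s.times, s.values, lam=None)
    if smoothing == 0:
        return make_interp_spline(s.times, s.values, k=3)
    if isinstance(smoothing, (int, float)) and smoothing > 0:
        return make_smoothing_spline(s.times, s.values, lam=float(smoothing))
    raise ValueError(f"invalid smoothing: {smoothing!r}")


@dataclass
class TurningPointResult:
    """Turning points of a fitted growth spline.

    ``turning_points`` are the supra-threshold local maxima of the signed
    second derivative, ordered by decreasing magnitude; ``primary`` is the
    global maximum, or ``None`` when curvature is essentially constant
    (``degenerate``).
    """

    grid: np.ndarray
    second_derivative: np.ndarray
    turning_points: list[float]
    primary: float | None
    degenerate: bool


def turning_points(
    spline: BSpline,
    t_min: float,
    t_max: float,
    step: float = 0.1,
    threshold: float = 0.5,
) -> TurningPointResult:
    """Locate trend turning points from the spline's second derivative.

    The second derivative is evaluated on a dense grid (``step`` s);
    interior and boundary local maxima whose value exceeds ``threshold``
    times the global maximum are reported, the global maximum first.
    Near-constant curvature (e.g. a purely quadratic trend) yields the
    explicit no-turning-point state rather than an arbitrary time.
    """
    grid = np.arange(t_min, t_max + step / 2.0, step)
    d2 = spline.derivative(2)(grid)
    span = float(np.ptp(d2))
    scale = max(1.0, float(np.max(np.abs(d2))) if d2.size else 0.0)
    if span <= 1e-6 * scale:
        return TurningPointResult(grid, d2, [], None, degenerate=True)

    maxima_idx = [
        i
        for i in range(len(d2))
        if (i == 0 or d2[i] >= d2[i - 1]) and (i == len(d2) - 1 or d2[i] >= d2[i + 1])
    ]
    global_max = float(np.max(d2))
    cut = threshold * global_max if global_max > 0 else global_max
    kept = [i for i in maxima_idx if d2[i] >= cut]
    kept.sort(key=lambda i: -d2[i])
    # collapse plateaus: drop maxima within one step of a stronger one
    times: list[float] = []
    for i in kept:
        if all(abs(grid[i] - t) > step * 1.5 for t in times):
            times.append(float(grid[i]))
    return TurningPointResult(grid, d2, times, times[0], degenerate=False)


class GrowthCurveModel:
    """Growth-curve model of one cycle-averaged trend.

    Parameters
    ----------
    series : CycleSeries
        The trend to model.
    smoothing : "gcv", 0 or positive float
        Spline penalty selection (see :func:`fit_growth_spline`).
    """

    def __init__(self, series: CycleSeries, smoothing: float | str = "gcv"):
        self.series = series.dropna()
        self.smoothing = smoothing

    def fit(self) -> "GrowthCurveResults":
        spline = fit_growth_spline(self.series, self.smoothing)
        return GrowthCurveResults(self, spline)


class GrowthCurveResults:
    """Fitted growth curve: evaluable trend, curvature and turning
    points."""

    def __init__(self, model: GrowthCurveModel, spline: BSpline):
        self.model = model
        self.spline = spline

    def predict(self, t) -> np.ndarray:
        return self.spline(np.asarray(t, dtype=float))

    def second_derivative(self, t) -> np.ndarray:
        return self.spline.derivative(2)(np.asarray(t, dtype=float))

    def turning_points(self, step: float = 0.1, threshold: float = 0.5
                       ) -> TurningPointResult:
        s = self.model.series
        return turning_points(
            self.spline, float(s.times[0]), float(s.times[-1]),
            step=step, threshold=threshold,
        )

    def summary(self) -> str:
        tp = self.turning_points()
        label = ", ".join(f"{k}={v}" for k, v in self.model.series.label.items())
        lines = [
            f"Growth-curve model ({label or 'all data'})",
            f"  points: {self.model.series.times.size}, smoothing: {self.model.smoothing}",
        ]
        if tp.degenerate:
            lines.append("  turning points: none (constant curvature)")
        else:
            pts = ", ".join(f"{t:.1f} s" for t in tp.turning_points)
            lines.append(f"  turning points: {pts} (primary {tp.primary:.1f} s)")
        return "\n".join(lines)

    def plot(self, ax=None, step: float = 0.1):
        """Trend + second-derivative figure (two stacked axes)."""
        import matplotlib.pyplot as plt

        s = self.model.series
        if ax is None:
            _, ax = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
        dense = np.arange(s.times[0], s.times[-1] + step / 2, step)
        ax[0].plot(s.times, s.values, "o", ms=3, label="cycle means")
        ax[0].plot(dense, self.predict(dense), "-", label="spline")
        ax[0].set_ylabel("value (ms)")
        ax[0].legend(frameon=False)
        ax[1].plot(dense, self.second_derivative(dense), "-")
        tp = self.turning_points(step=step)
        for t in tp.turning_points:
            ax[1].axvline(t, color="tab:orange", ls="--", lw=1)
        ax[1].set_xlabel("time (s)")
        ax[1].set_ylabel("2nd derivative")
        return ax
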