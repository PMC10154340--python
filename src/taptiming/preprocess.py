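"""Outlier rejection and bootstrap balancing applied before inference.

Gross-error observations are removed with Tukey fences computed within
condition cells: values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` (k = 1.5 by
default) are dropped and accounted for per cell.  The filtered cells are
then balanced to a constant per-cell sample size by bootstrap resampling
(with replacement by default, m = 5), so condition comparisons are not
driven by unequal cell counts after misses and rejections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["OutlierRule", "BalanceRule", "iqr_filter", "iqr_filter_frame", "bootstrap_balance"]

DEFAULT_GROUPING = ["participant_id", "design", "mode", "phase"]


@dataclass(frozen=True)
class OutlierRule:
    """Tukey-fence outlier rule: drop values outside
    ``[Q1 - k*IQR, Q3 + k*IQR]`` with ``IQR = Q3 - Q1``.

    Quartiles use linear interpolation between order statistics.
    ``grouping`` names the condition cells within which fences are
    computed.
    """

    k: float = 1.5
    grouping: tuple[str, ...] = tuple(DEFAULT_GROUPING)
    min_group_size: int = 4

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")

    def fences(self, values) -> tuple[float, float]:
        q1, q3 = np.percentile(np.asarray(values, dtype=float), [25, 75])
        iqr = q3 - q1
        return q1 - self.k * iqr, q3 + self.k * iqr


@dataclass(frozen=True)
class BalanceRule:
    """Bootstrap-balancing rule: resample every condition block to exactly
    ``m`` values (with replacement by default), deterministically in
    ``seed``."""

    m: int = 5
    with_replacement: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")


def iqr_filter(values, rule: OutlierRule | None = None):
    """Filter one group of values by the Tukey fences.

    Returns ``(kept, removed)`` arrays.  Groups smaller than
    ``rule.min_group_size`` are passed through untouched with a warning
    (quartiles of a handful of points are meaningless).
    """
    rule = rule or OutlierRule()
    vals = np.asarray(values, dtype=float)
    if vals.size < rule.min_group_size:
        warnings.warn(
            f"group of size {vals.size} < {rule.min_group_size}: "
            "outlier filter skipped", stacklevel=2
        )
        return vals, np.empty(0)
    lo, hi = rule.fences(vals)
    keep = (vals >= lo) & (vals <= hi)
    return vals[keep], vals[~keep]


def iqr_filter_frame(
    df: pd.DataFrame,
    value_col: str,
    rule: OutlierRule | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Apply the Tukey-fence filter within each condition cell of a tidy
    table.

    Returns ``(kept, removed, report)``; the report counts rows before,
    removed and after per cell (the missing-data accounting).
    """
    rule = rule or OutlierRule()
    grouping = [c for c in rule.grouping if c in df.columns]
    if not grouping:
        raise ValueError("none of the grouping columns are present")
    kept_parts, removed_parts, report_rows = [], [], []
    for key, g in df.groupby(grouping, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = g[value_col].to_numpy(dtype=float)
        if vals.size < rule.min_group_size:
            warnings.warn(
                f"condition cell {key} has {vals.size} < {rule.min_group_size} "
                "values: outlier filter skipped", stacklevel=2
            )
            kept_parts.append(g)
            n_removed = 0
        else:
            lo, hi = rule.fences(vals)
            mask = (vals >= lo) & (vals <= hi)
            kept_parts.append(g[mask])
            removed_parts.append(g[~mask])
            n_removed = int((~mask).sum())
        report_rows.append(
            dict(zip(grouping, key))
            | {"n_before": len(g), "n_removed": n_removed, "n_after": len(g) - n_removed}
        )
    kept = pd.concat(kept_parts) if kept_parts else df.iloc[0:0]
    removed = pd.concat(removed_parts) if removed_parts else df.iloc[0:0]
    report = pd.DataFrame(report_rows)
    return kept.reset_index(drop=True), removed.reset_index(drop=True), report


def bootstrap_balance(
    df: pd.DataFrame,
    rule: BalanceRule | None = None,
    grouping: list[str] | None = None,
) -> pd.DataFrame:
    """Resample every condition block of a tidy table to exactly
    ``rule.m`` rows.

    With replacement (true bootstrap) by default; without replacement only
    when the block already has at least ``m`` rows, in which case a
    deterministic subsample is drawn.  An empty block raises, naming the
    condition.
    """
    rule = rule or BalanceRule()
    grouping = grouping or [c for c in DEFAULT_GROUPING if c in df.columns]
    rng = np.random.default_rng(rule.seed)
    parts = []
    for key, g in df.groupby(grouping, sort=True):
        if len(g) == 0:  # pragma: no cover - pandas drops empty groups
            raise ValueError(f"empty condition block: {key}")
        if rule.with_replacement:
            idx = rng.integers(0, len(g), size=rule.m)
        else:
            if len(g) < rule.m:
                raise ValueError(
                    f"condition block {key} has {len(g)} < m={rule.m} rows and "
                    "with_replacement is off"
                )
            idx = rng.permutation(len(g))[: rule.m]
        parts.append(g.iloc[idx])
    if not parts:
        raise ValueError("no condition blocks present")
    return pd.concat(parts).reset_index(drop=True)
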