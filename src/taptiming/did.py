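"""Difference-in-differences estimation of the study-design effect.

The pacing-to-continuation transition cannot be randomized within a
participant, so the causal effect of the trial-ordering design on a
timing index is estimated by difference-in-differences: the blocked
group is the control, the alternating group the manipulated group, and
phase plays the role of time (pacing = pre, continuation = post).  With
dummy-coded time ``P`` (continuation = 1) and group ``G``
(alternating = 1), the OLS model is

    Y = b0 + b1 P + b2 G + b3 (P x G) + eps

* ``b0`` -- baseline: control-group (blocked) pacing mean;
* ``b1`` -- pacing-to-continuation change in the control group;
* ``b2`` -- group difference at pacing;
* ``b3`` -- the DID interaction, the causal design effect under the
  parallel-trends assumption (both groups would have changed equally
  absent the manipulation).  Parallel trends is an assumption here, not
  a tested hypothesis.

On a balanced design the coefficients reduce to cell-mean arithmetic:
``b3 = (ym_post - ym_pre) - (yc_post - yc_pre)`` exactly.

Report row labels follow the convention of naming the time dummies after
the groups they apply to: "Block" is the control-group time change
(``b1``), "Alternating" the group offset (``b2``), and
"Block x Alternating" the interaction (``b3``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

__all__ = [
    "build_did_matrix",
    "DifferenceInDifferences",
    "DIDResults",
    "did_report",
]

COEF_NAMES = ["const", "time", "group", "time_x_group"]
REPORT_LABELS = {
    "const": "Constant",
    "time": "Block",
    "group": "Alternating",
    "time_x_group": "Block x Alternating",
}


def _encode(values, mapping: dict | None, name: str) -> np.ndarray:
    v = np.asarray(values)
    if mapping:
        out = np.full(v.shape, -1.0)
        for label, code in mapping.items():
            out[v == label] = code
        if np.any(out < 0):
            bad = sorted(set(v[out < 0].tolist()))
            raise ValueError(f"unrecognized {name} labels: {bad}")
        return out
    out = v.astype(float)
    if not set(np.unique(out)) <= {0.0, 1.0}:
        raise ValueError(f"{name} must be coded 0/1 or mapped labels")
    return out


def build_did_matrix(
    group,
    time,
    group_map: dict | None = None,
    time_map: dict | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Canonical DID design matrix: intercept, time dummy, group dummy,
    time x group interaction.

    ``group``/``time`` are 0/1 arrays or label arrays with the
    corresponding maps (e.g. ``{"blocked": 0, "alternating": 1}``,
    ``{"pacing": 0, "continuation": 1}``).  All four cells must be
    occupied; an empty cell is named in the error.
    """
    g = _encode(group, group_map, "group")
    p = _encode(time, time_map, "time")
    for gv in (0, 1):
        for pv in (0, 1):
            if not np.any((g == gv) & (p == pv)):
                raise ValueError(
                    f"empty DID cell: group={'manipulated' if gv else 'control'}, "
                    f"time={'post' if pv else 'pre'}"
                )
    X = np.column_stack([np.ones_like(g), p, g, p * g])
    return X, list(COEF_NAMES)


class DifferenceInDifferences:
    """DID model of a timing index on study design and phase.

    Parameters
    ----------
    data : DataFrame
        Observation table (typically trial-phase means) with the outcome
        column plus group and time columns.
    outcome : str
        Outcome column, e.g. ``"asynchrony_ms"`` or ``"iri_ms"``.
    group_col, time_col : str
        Column names (defaults ``design``, ``phase``).
    control, treated, pre, post : str
        Labels mapping onto the dummies (defaults: blocked vs
        alternating; pacing vs continuation).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        group_col: str = "design",
        time_col: str = "phase",
        control: str = "blocked",
        treated: str = "alternating",
        pre: str = "pacing",
        post: str = "continuation",
    ):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.group_col = group_col
        self.time_col = time_col
        self.group_map = {control: 0, treated: 1}
        self.time_map = {pre: 0, post: 1}

    def fit(self) -> "DIDResults":
        X, names = build_did_matrix(
            self.data[self.group_col],
            self.data[self.time_col],
            group_map=self.group_map,
            time_map=self.time_map,
        )
        y = self.data[self.outcome].to_numpy(dtype=float)
        res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
        return DIDResults(self, res)


class DIDResults:
    """Fitted DID model: the four coefficients with inference, fit
    statistics and residual-shape diagnostics."""

    def __init__(self, model: DifferenceInDifferences, sm_results):
        self.model = model
        self._res = sm_results

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def fvalue(self) -> float:
        return float(self._res.fvalue)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self._res.resid)

    @property
    def effect(self) -> float:
        """The causal design effect: the time x group interaction."""
        return float(self.params["time_x_group"])

    @property
    def residual_skewness(self) -> float:
        return float(st.skew(self.resid))

    @property
    def residual_kurtosis(self) -> float:
        """Pearson (non-excess) kurtosis; 3 for a normal distribution."""
        return float(st.kurtosis(self.resid, fisher=False))

    def cell_means(self) -> pd.DataFrame:
        """Observed group x time cell means (the DID arithmetic inputs)."""
        d = self.model.data
        g = d[self.model.group_col].map(self.model.group_map)
        p = d[self.model.time_col].map(self.model.time_map)
        return (
            d.assign(_g=g, _p=p)
            .groupby(["_g", "_p"])[self.model.outcome]
            .mean()
            .rename("mean")
            .reset_index()
            .rename(columns={"_g": "group", "_p": "time"})
        )

    def summary(self) -> str:
        degenerate = bool(np.allclose(self.resid, 0.0))
        lines = [
            "Difference-in-differences (OLS)",
            f"  outcome: {self.model.outcome}, n = {self.nobs}, "
            f"R^2 = {self.rsquared:.4f}",
            f"  residual kurtosis = {self.residual_kurtosis:.3f}, "
            f"skewness = {self.residual_skewness:.3f}",
            "  note: 'Block'/'Alternating' rows are the time dummies of the",
            "  control and manipulated groups (canonical coding: time, group,",
            "  time x group); parallel trends assumed, not tested.",
            "",
            f"  {'term':22s} {'beta':>10s} {'SE':>9s} {'t':>9s}",
        ]
        for name in COEF_NAMES:
            b = self.params[name]
            se = self.bse[name]
            t = self.tvalues[name]
            lines.append(
                f"  {REPORT_LABELS[name]:22s} {b:10.3f} {se:9.3f} "
                + (f"{t:9.3f}" if np.isfinite(t) else "      inf")
            )
        if degenerate:
            lines.append("  (zero residuals: SEs degenerate)")
        return "\n".join(lines)


def did_report(result: DIDResults) -> pd.DataFrame:
    """Coefficient table with the conventional row labels plus the
    observation count."""
    rows = [
        {
            "term": REPORT_LABELS[name],
            "beta": float(result.params[name]),
            "se": float(result.bse[name]),
            "t": float(result.tvalues[name]),
        }
        for name in COEF_NAMES
    ]
    rows.append({"term": "Obs", "beta": float(result.nobs), "se": np.nan, "t": np.nan})
    return pd.DataFrame(rows)
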