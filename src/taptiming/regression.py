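"""Multiple regression of the timing indices on mode, phase and design.

The observation unit is the trial-phase mean of a timing index
(asynchrony or IRI) after preprocessing.  The model regresses that
outcome on dummy-coded tapping mode, maintenance phase and study design
(reference levels: synchronized, pacing, blocked), optionally with all
two-way interactions, fitted by ordinary least squares:

    Y = X beta + eps

`TimingRegression` is the model object; its `fit()` returns a
`TimingRegressionResults` carrying coefficients with standard errors,
R-squared, the overall F test, and a per-factor effect table (Type-III
style full-vs-reduced F tests with partial eta-squared).  Tukey's HSD
handles pairwise condition contrasts, and `posthoc_power` gives the
noncentral-F power of the overall regression F test at a given Cohen's f.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf

__all__ = [
    "OLSFit",
    "fit_ols",
    "trial_phase_means",
    "TimingRegression",
    "TimingRegressionResults",
    "tukey_hsd",
    "PowerSpec",
    "posthoc_power",
]

REFERENCE_LEVELS = {"mode": "synchronized", "phase": "pacing", "design": "blocked"}


# ---------------------------------------------------------------------------
# low-level OLS on an explicit design matrix

@dataclass
class OLSFit:
    """Closed-form OLS solution on an explicit design matrix."""

    params: np.ndarray
    bse: np.ndarray
    resid: np.ndarray
    fitted: np.ndarray
    rsquared: float
    fvalue: float
    df_model: int
    df_resid: int
    names: list[str]

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse


def fit_ols(y, X, names: list[str] | None = None) -> OLSFit:
    """Solve ``min ||y - X b||^2`` by the normal equations.

    Standard errors use the unbiased residual variance
    ``s^2 = RSS / (n - p)``.  A rank-deficient ``X`` raises, naming the
    collinear columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = names or [f"x{j}" for j in range(p)]
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    fitted = X @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    s2 = rss / (n - p)
    bse = np.sqrt(np.diag(s2 * np.linalg.inv(XtX)))
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    df_model = p - 1
    if df_model > 0 and rss > 0:
        fval = (tss - rss) / df_model / (rss / (n - p))
    else:
        fval = np.inf if df_model > 0 else np.nan
    return OLSFit(beta, bse, resid, fitted, r2, fval, df_model, n - p, list(names))


# ---------------------------------------------------------------------------
# observation table

def trial_phase_means(df: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Collapse a tidy per-tap table to trial-phase means, the regression
    observation unit."""
    keys = ["participant_id", "design", "mode", "phase", "trial"]
    out = df.groupby(keys, sort=True)[value_col].mean().reset_index()
    return out


# ---------------------------------------------------------------------------
# model object

class TimingRegression:
    """OLS regression of a timing index on mode, phase and design.

    Parameters
    ----------
    data : DataFrame
        Observation table with the outcome column plus categorical
        ``mode``, ``phase`` and ``design`` columns (use
        :func:`trial_phase_means` to build it from tap events).
    outcome : str
        Outcome column name, e.g. ``"asynchrony_ms"`` or ``"iri_ms"``.
    factors : sequence of str
        Categorical predictors (default mode, phase, design; a factor
        absent from the data is dropped).
    interactions : bool
        Include all two-way interactions between the factors.
    """

    def __init__(self, data: pd.DataFrame, outcome: str,
                 factors=("mode", "phase", "design"), interactions: bool = True):
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.factors = [f for f in factors if f in data.columns and data[f].nunique() > 1]
        if not self.factors:
            raise ValueError("no usable factors in data")
        self.interactions = interactions

    @classmethod
    def from_events(cls, events: pd.DataFrame, value_col: str, **kwargs
                    ) -> "TimingRegression":
        return cls(trial_phase_means(events, value_col), outcome=value_col, **kwargs)

    def _term(self, factor: str) -> str:
        ref = REFERENCE_LEVELS.get(factor)
        if ref is not None and ref in set(self.data[factor]):
            return f"C({factor}, Treatment(reference='{ref}'))"
        return f"C({factor})"

    def _terms(self) -> list[str]:
        terms = [self._term(f) for f in self.factors]
        if self.interactions:
            terms += [
                f"{self._term(a)}:{self._term(b)}"
                for a, b in itertools.combinations(self.factors, 2)
            ]
        return terms

    @property
    def formula(self) -> str:
        return f"{self.outcome} ~ " + " + ".join(self._terms())

    def fit(self) -> "TimingRegressionResults":
        res = smf.ols(self.formula, data=self.data).fit()
        return TimingRegressionResults(self, res)


class TimingRegressionResults:
    """Fitted timing regression: coefficients, fit statistics and the
    per-factor effect table."""

    def __init__(self, model: TimingRegression, sm_results):
        self.model = model
        self._res = sm_results

    # pass-through fit quantities
    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def resid(self) -> pd.Series:
        return self._res.resid

    @property
    def fittedvalues(self) -> pd.Series:
        return self._res.fittedvalues

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def fvalue(self) -> float:
        return float(self._res.fvalue)

    @property
    def df_model(self) -> int:
        return int(self._res.df_model)

    @property
    def df_resid(self) -> int:
        return int(self._res.df_resid)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def effect_table(self) -> pd.DataFrame:
        """Per-term F tests (full vs term-dropped model) with partial
        eta-squared ``SS_effect / (SS_effect + SS_error)``."""
        full = self._res
        sse_full = float(full.ssr)
        rows = []
        terms = self.model._terms()
        labels = self.model.factors + (
            [f"{a}:{b}" for a, b in itertools.combinations(self.model.factors, 2)]
            if self.model.interactions
            else []
        )
        for label, term in zip(labels, terms):
            reduced_terms = [t for t in terms if t != term]
            formula = self.model.outcome + " ~ " + (" + ".join(reduced_terms) or "1")
            red = smf.ols(formula, data=self.model.data).fit()
            ss_effect = float(red.ssr) - sse_full
            df_effect = int(red.df_resid - full.df_resid)
            if df_effect <= 0:
                continue
            ms_error = sse_full / full.df_resid
            fval = (ss_effect / df_effect) / ms_error if ms_error > 0 else np.inf
            pval = st.f.sf(fval, df_effect, full.df_resid)
            eta2 = ss_effect / (ss_effect + sse_full) if (ss_effect + sse_full) > 0 else 0.0
            rows.append(
                {
                    "term": label,
                    "df1": df_effect,
                    "df2": int(full.df_resid),
                    "F": fval,
                    "p": pval,
                    "partial_eta2": eta2,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Timing regression (OLS)",
            f"  formula: {self.model.formula}",
            f"  n = {self.nobs}, R^2 = {self.rsquared:.4f}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f}",
            "",
            "  Coefficients (beta +/- SE):",
        ]
        for name, b, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"    {name:60s} {b:10.3f} +/- {se:8.3f}")
        et = self.effect_table()
        if len(et):
            lines += ["", "  Effects (full vs dropped-term F):"]
            for _, r in et.iterrows():
                lines.append(
                    f"    {r['term']:20s} F({r['df1']},{r['df2']}) = {r['F']:8.2f}, "
                    f"p = {r['p']:.3g}, partial eta^2 = {r['partial_eta2']:.3f}"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Tukey HSD

def tukey_hsd(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean contrasts with studentized-range inference
    (Tukey-Kramer for unequal group sizes).

    Returns a table with columns group1, group2, diff, se, q, q_crit, p,
    significant.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    k = len(arrays)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df_w = int(ns.sum() - k)
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    msw = ssw / df_w
    q_crit = st.studentized_range.ppf(1 - alpha, k, df_w)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else np.inf)
        p = float(st.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
        rows.append(
            {
                "group1": labels[i],
                "group2": labels[j],
                "diff": diff,
                "se": se,
                "q": q,
                "q_crit": q_crit,
                "p": p,
                "significant": bool(q > q_crit),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# post-hoc power

@dataclass(frozen=True)
class PowerSpec:
    """Inputs of a post-hoc power computation for the overall regression
    F test: Cohen's f, sample size, predictor count, alpha."""

    effect_size_f: float
    n: int
    predictors: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ValueError("effect_size_f must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def posthoc_power(spec: PowerSpec) -> float:
    """Power of the overall regression F test.

    ``df1 = predictors``, ``df2 = n - predictors - 1``, noncentrality
    ``lambda = f^2 * n``; power is the noncentral-F survival probability
    at the central-F critical value.  ``f = 0`` gives exactly alpha.
    """
    df1 = spec.predictors
    df2 = spec.n - spec.predictors - 1
    if df2 < 1:
        raise ValueError(f"n={spec.n} too small for {spec.predictors} predictors")
    fcrit = st.f.ppf(1 - spec.alpha, df1, df2)
    if spec.effect_size_f == 0:
        return float(spec.alpha)
    lam = spec.effect_size_f**2 * spec.n
    return float(st.ncf.sf(fcrit, df1, df2, lam))
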