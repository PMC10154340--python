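"""Session file handling, run configuration and the end-to-end pipeline.

Sessions are stored as tidy CSV, one row per registered tap::

    participant_id, design, mode, phase, trial, cycle,
    raw_tap_ms, tap_ms, target_ms

A run is described by a :class:`RunConfig` (serializable to YAML); every
report bundle carries a snapshot of its config plus the snapshot's
content hash, so outputs are attributable to an exact configuration and
two runs with the same config and seed produce identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics, preprocess
from .design import DesignKind, Mode, ModeOrder, Phase, TaskDesign, build_default_design
from .did import DifferenceInDifferences, did_report
from .growthcurve import GrowthCurveModel, cycle_average
from .regression import (
    PowerSpec,
    TimingRegression,
    posthoc_power,
    trial_phase_means,
    tukey_hsd,
)
from .simulate import (
    GeneratorParams,
    Session,
    TapEvent,
    Trial,
    alternating_design_params,
    block_design_params,
    make_metronome,
    sessions_to_frame,
    simulate_cohort,
)

logger = logging.getLogger("taptiming")

SESSION_COLUMNS = [
    "participant_id", "design", "mode", "phase", "trial", "cycle",
    "raw_tap_ms", "tap_ms", "target_ms",
]

STAGES = ["simulate", "metrics", "preprocess", "analyze"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


# ---------------------------------------------------------------------------
# session CSV

def write_session_csv(frame_or_sessions, path, config_hash: str | None = None) -> None:
    """Write a tidy tap-event table (or list of sessions) to CSV; an
    optional config hash is recorded as a leading comment line."""
    if isinstance(frame_or_sessions, pd.DataFrame):
        frame = frame_or_sessions
    else:
        frame = sessions_to_frame(frame_or_sessions)
    path = Path(path)
    with open(path, "w") as fh:
        if config_hash:
            fh.write(f"# config_sha: {config_hash}\n")
        # %.17g guarantees exact float round trips through the CSV
        frame.to_csv(fh, index=False, float_format="%.17g")


def read_session_frame(path) -> pd.DataFrame:
    """Read a session CSV back into the tidy tap-event table.

    Malformed rows (non-numeric times/indices) are dropped and logged
    with their line numbers; a missing column is a schema error.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty and df.columns.size == 0:
        raise ValueError(f"{path}: empty session file")
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: schema mismatch, missing columns {missing}")
    numeric = ["trial", "cycle", "raw_tap_ms", "tap_ms", "target_ms"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based counting (comment lines shift this
        # by however many there are; good enough for diagnostics)
        for idx in df.index[bad]:
            logger.warning("%s: dropping malformed row at line ~%d", path, idx + 2)
    df = df.loc[~bad].copy()
    df[numeric] = coerced.loc[~bad]
    df["trial"] = df["trial"].astype(int)
    df["cycle"] = df["cycle"].astype(int)
    for col in ("raw_tap_ms", "tap_ms", "target_ms"):
        df[col] = df[col].astype(float)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    return df.reset_index(drop=True)


def read_session_csv(path, design: TaskDesign | None = None) -> list[Session]:
    """Read a session CSV into typed :class:`Session` objects.

    ``design`` supplies the task constants for reconstructing metronome
    beat trains (default configuration if omitted).
    """
    design = design or build_default_design()
    df = read_session_frame(path)
    sessions: list[Session] = []
    for pid, g in df.groupby("participant_id", sort=False):
        design_kind = DesignKind(g["design"].iloc[0])
        trials: list[Trial] = []
        for trial_index, t in g.groupby("trial", sort=True):
            mode = Mode(t["mode"].iloc[0])
            events = [
                TapEvent(
                    participant_id=str(pid),
                    trial_index=int(trial_index),
                    cycle_index=int(r.cycle),
                    mode=mode,
                    phase=Phase(r.phase),
                    raw_tap_time=float(r.raw_tap_ms),
                    tap_time=float(r.tap_ms),
                    target_time=float(r.target_ms),
                )
                for r in t.sort_values("cycle").itertuples()
            ]
            trials.append(
                Trial(
                    trial_index=int(trial_index),
                    mode=mode,
                    events=events,
                    beats=make_metronome(design),
                )
            )
        first_mode = trials[0].mode if trials else Mode.SYNCHRONIZED
        order = (
            ModeOrder.SYNC_FIRST
            if first_mode is Mode.SYNCHRONIZED
            else ModeOrder.SYNCOPATION_FIRST
        )
        sessions.append(
            Session(
                participant_id=str(pid),
                design_kind=design_kind,
                mode_order=order,
                trials=trials,
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# run configuration

@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    n_block: int = 10
    n_alternating: int = 13
    seed: int = 0
    design: dict = field(default_factory=dict)  # TaskDesign field overrides
    params_block: dict = field(default_factory=dict)  # GeneratorParams overrides
    params_alternating: dict = field(default_factory=dict)
    iqr_k: float = 1.5
    balance_m: int = 5
    balance: bool = True
    smoothing: float | str = "gcv"
    power_f: tuple[float, ...] = (0.14, 0.39, 0.59)
    power_n: int = 23
    power_predictors: int = 3
    alpha: float = 0.05
    stop_after: str = "analyze"
    log_level: str = "INFO"

    def task_design(self, kind: DesignKind = DesignKind.BLOCKED) -> TaskDesign:
        return build_default_design(**self.design).replace(design_kind=kind)

    def generator_params(self) -> dict[DesignKind, GeneratorParams]:
        return {
            DesignKind.BLOCKED: block_design_params(**self.params_block),
            DesignKind.ALTERNATING: alternating_design_params(**self.params_alternating),
        }

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["power_f"] = list(self.power_f)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text) or {}
        if "power_f" in d:
            d["power_f"] = tuple(d["power_f"])
        return cls(**d)

    @property
    def content_hash(self) -> str:
        """Short sha256 of the canonical YAML snapshot."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# pipeline

def _write_csv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha: {config_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run simulate -> metrics -> preprocess -> analyze, writing a report
    bundle to ``out_dir``.

    Returns a manifest dict (also written as ``manifest.json``) naming
    every artifact and the config hash.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.content_hash
    (out / "config.yaml").write_text(config.to_yaml())
    artifacts: dict[str, str] = {"config": "config.yaml"}
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))

    def done(stage: str) -> bool:
        return STAGES.index(config.stop_after) <= STAGES.index(stage)

    # --- simulate -----------------------------------------------------
    try:
        sessions = simulate_cohort(
            config.n_block,
            config.n_alternating,
            config.generator_params(),
            seed=config.seed,
            design=config.task_design(),
        )
        events = sessions_to_frame(sessions)
        write_session_csv(events, out / "sessions.csv", config_hash=h)
        artifacts["sessions"] = "sessions.csv"
        logger.info("simulate: %d sessions, %d tap events", len(sessions), len(events))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", e) from e
    if done("simulate"):
        return _finish(out, h, artifacts)

    # --- metrics ------------------------------------------------------
    try:
        asyn = metrics.asynchrony_frame(events)
        iris = metrics.iri_frame(events)
        _write_csv(metrics.summarize(asyn, "asynchrony_ms"),
                   out / "summary_asynchrony.csv", h)
        _write_csv(metrics.summarize(iris, "iri_ms"), out / "summary_iri.csv", h)
        artifacts["summary_asynchrony"] = "summary_asynchrony.csv"
        artifacts["summary_iri"] = "summary_iri.csv"
        logger.info("metrics: %d asynchronies, %d IRIs", len(asyn), len(iris))
    except Exception as e:  # noqa: BLE001
        raise PipelineError("metrics", e) from e
    if done("metrics"):
        return _finish(out, h, artifacts)

    # --- preprocess ---------------------------------------------------
    try:
        rule = preprocess.OutlierRule(k=config.iqr_k)
        asyn_kept, _, asyn_rep = preprocess.iqr_filter_frame(asyn, "asynchrony_ms", rule)
        iri_kept, _, iri_rep = preprocess.iqr_filter_frame(iris, "iri_ms", rule)
        _write_csv(asyn_rep, out / "outlier_report_asynchrony.csv", h)
        _write_csv(iri_rep, out / "outlier_report_iri.csv", h)
        artifacts["outlier_report_asynchrony"] = "outlier_report_asynchrony.csv"
        artifacts["outlier_report_iri"] = "outlier_report_iri.csv"
        balance_grouping = ["participant_id", "design", "mode", "phase", "trial"]
        if config.balance:
            brule = preprocess.BalanceRule(m=config.balance_m, seed=config.seed)
            asyn_bal = preprocess.bootstrap_balance(asyn_kept, brule, balance_grouping)
            iri_bal = preprocess.bootstrap_balance(iri_kept, brule, balance_grouping)
        else:
            asyn_bal, iri_bal = asyn_kept, iri_kept
        logger.info(
            "preprocess: asynchrony %d -> %d rows, IRI %d -> %d rows",
            len(asyn), len(asyn_bal), len(iris), len(iri_bal),
        )
    except Exception as e:  # noqa: BLE001
        raise PipelineError("preprocess", e) from e
    if done("preprocess"):
        return _finish(out, h, artifacts)

    # --- analyze ------------------------------------------------------
    try:
        turning: dict[str, dict] = {}
        for name, frame, col in [
            ("asynchrony", asyn_bal, "asynchrony_ms"),
            ("iri", iri_bal, "iri_ms"),
        ]:
            obs = trial_phase_means(frame, col)
            fit = TimingRegression(obs, outcome=col).fit()
            coefs = pd.DataFrame(
                {"term": fit.params.index, "beta": fit.params.to_numpy(),
                 "se": fit.bse.to_numpy()}
            )
            _write_csv(coefs, out / f"regression_{name}.csv", h)
            _write_csv(fit.effect_table(), out / f"effects_{name}.csv", h)
            artifacts[f"regression_{name}"] = f"regression_{name}.csv"
            artifacts[f"effects_{name}"] = f"effects_{name}.csv"

            cells = {
                f"{d}/{m}/{p}": g[col].to_numpy()
                for (d, m, p), g in obs.groupby(["design", "mode", "phase"])
                if len(g) >= 2
            }
            if len(cells) >= 2:
                _write_csv(tukey_hsd(cells, alpha=config.alpha),
                           out / f"tukey_{name}.csv", h)
                artifacts[f"tukey_{name}"] = f"tukey_{name}.csv"

            # growth curves and turning points per design
            trend_rows = []
            for series in cycle_average(frame, col, grouping=["design"],
                                        design=config.task_design()):
                gfit = GrowthCurveModel(series, smoothing=config.smoothing).fit()
                tp = gfit.turning_points()
                label = series.label.get("design", "all")
                trend_rows.append(
                    pd.DataFrame(
                        {
                            "design": label,
                            "time_s": series.times,
                            "value_ms": series.values,
                            "fitted_ms": gfit.predict(series.times),
                        }
                    )
                )
                turning.setdefault(name, {})[label] = {
                    "primary_s": tp.primary,
                    "turning_points_s": tp.turning_points,
                    "degenerate": tp.degenerate,
                }
            _write_csv(pd.concat(trend_rows, ignore_index=True),
                       out / f"trend_{name}.csv", h)
            artifacts[f"trend_{name}"] = f"trend_{name}.csv"

            did_fit = DifferenceInDifferences(obs, outcome=col).fit()
            _write_csv(did_report(did_fit), out / f"did_{name}.csv", h)
            artifacts[f"did_{name}"] = f"did_{name}.csv"
            turning.setdefault("did", {})[name] = {
                "effect": did_fit.effect,
                "rsquared": did_fit.rsquared,
                "nobs": did_fit.nobs,
                "residual_kurtosis": did_fit.residual_kurtosis,
                "residual_skewness": did_fit.residual_skewness,
            }

        power = pd.DataFrame(
            [
                {
                    "cohens_f": f,
                    "n": config.power_n,
                    "predictors": config.power_predictors,
                    "alpha": config.alpha,
                    "power": posthoc_power(
                        PowerSpec(f, config.power_n, config.power_predictors,
                                  config.alpha)
                    ),
                }
                for f in config.power_f
            ]
        )
        _write_csv(power, out / "power.csv", h)
        artifacts["power"] = "power.csv"

        report = {"config_sha": h, "turning_points": turning}
        (out / "analysis.json").write_text(json.dumps(report, indent=2))
        artifacts["analysis"] = "analysis.json"
        logger.info("analyze: wrote %d artifacts", len(artifacts))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("analyze", e) from e

    return _finish(out, h, artifacts)


def _finish(out: Path, h: str, artifacts: dict) -> dict:
    manifest = {"config_sha": h, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
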