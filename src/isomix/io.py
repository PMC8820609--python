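"""Delimited-text and config serialization.

Time series travel as headed CSV (``time_d, delta_permil``); multi-source
tables put one column per source after ``time_d``.  Scenario configs are
plain dicts round-tripped through JSON or YAML, keys mirroring the
dataclass fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .forcing import (
    BrownianSpec,
    ConstantSourcesSpec,
    SourcePool,
    TimeSeries,
    TurnoverSchedule,
    make_turnover,
)
from .dmm import ConsumerTrajectory, ScenarioConfig
from .invert import InversionResult
from .smm import DietEstimate

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_consumer",
    "read_consumer",
    "read_sources",
    "write_sources",
    "read_lambda_table",
    "write_lambda_table",
    "write_estimate",
    "write_inversion",
    "config_to_dict",
    "config_from_dict",
    "load_config",
    "dump_config",
]


def read_timeseries(path, label: str = "") -> TimeSeries:
    df = pd.read_csv(path)
    if "time_d" not in df.columns:
        raise InvalidInputError(f"{path}: missing required 'time_d' column")
    value_cols = [c for c in df.columns if c != "time_d"]
    if len(value_cols) != 1:
        raise InvalidInputError(f"{path}: expected exactly one value column")
    return TimeSeries(
        df["time_d"].to_numpy(float),
        df[value_cols[0]].to_numpy(float),
        label=label or value_cols[0],
    )


def write_timeseries(series: TimeSeries, path, value_column: str = "delta_permil"):
    pd.DataFrame(
        {"time_d": series.times, value_column: series.values}
    ).to_csv(path, index=False)


def write_consumer(traj: ConsumerTrajectory, path):
    pd.DataFrame(
        {
            "time_d": traj.consumer.times,
            "delta_c_permil": traj.consumer.values,
            "delta_target_permil": traj.diet_target.values,
        }
    ).to_csv(path, index=False)


def read_consumer(path) -> TimeSeries:
    """Read a consumer series from either a bare or a simulate-output CSV."""
    df = pd.read_csv(path)
    if "time_d" not in df.columns:
        raise InvalidInputError(f"{path}: missing required 'time_d' column")
    for col in ("delta_c_permil", "delta_permil"):
        if col in df.columns:
            return TimeSeries(
                df["time_d"].to_numpy(float), df[col].to_numpy(float), label="delta_c"
            )
    raise InvalidInputError(
        f"{path}: expected a 'delta_c_permil' or 'delta_permil' column"
    )


def read_sources(path, tdfs) -> SourcePool:
    """Read a pool from ``time_d`` plus one delta column per source."""
    df = pd.read_csv(path)
    if "time_d" not in df.columns:
        raise InvalidInputError(f"{path}: missing required 'time_d' column")
    value_cols = [c for c in df.columns if c != "time_d"]
    tdfs = tuple(float(v) for v in tdfs)
    if len(value_cols) != len(tdfs):
        raise InvalidInputError(
            f"{path}: {len(value_cols)} source columns but {len(tdfs)} "
            "discrimination factors"
        )
    times = df["time_d"].to_numpy(float)
    return SourcePool(
        tuple(
            (TimeSeries(times, df[c].to_numpy(float), label=c), tdf)
            for c, tdf in zip(value_cols, tdfs)
        )
    )


def write_sources(pool: SourcePool, path):
    base = pool.trajectories[0].times
    data = {"time_d": base}
    for i, ts in enumerate(pool.trajectories):
        if ts.times.shape != base.shape or np.any(ts.times != base):
            raise InvalidInputError(
                "source trajectories must share one grid to share a table"
            )
        data[ts.label or f"source_{i}"] = ts.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_lambda_table(path) -> TurnoverSchedule:
    df = pd.read_csv(path)
    required = {"start_d", "end_d", "lambda_per_d"}
    if not required.issubset(df.columns):
        raise InvalidInputError(f"{path}: expected columns {sorted(required)}")
    return make_turnover(
        "tabulated",
        table=list(zip(df["start_d"], df["end_d"], df["lambda_per_d"])),
    )


def write_lambda_table(turnover: TurnoverSchedule, path):
    if turnover.mode != "tabulated":
        raise InvalidInputError("only tabulated schedules have a table form")
    pd.DataFrame(
        turnover.table, columns=["start_d", "end_d", "lambda_per_d"]
    ).to_csv(path, index=False)


def write_estimate(estimate: DietEstimate, path):
    window = (
        estimate.window
        if estimate.window is not None
        else np.full(estimate.times.size, np.nan)
    )
    pd.DataFrame(
        {
            "time_d": estimate.times,
            "p_hat_a": estimate.p_hat,
            "in_polygon": estimate.in_polygon,
            "window_d": window,
        }
    ).to_csv(path, index=False)


def write_inversion(result: InversionResult, path):
    pd.DataFrame(
        {
            "start_d": [p[0] for p in result.periods],
            "end_d": [p[1] for p in result.periods],
            "p_hat_a": result.p_hat,
            "residual_permil": result.residual,
            "converged": result.converged,
        }
    ).to_csv(path, index=False)


def _sources_to_dict(sources, source_tdfs):
    if isinstance(sources, ConstantSourcesSpec):
        return {
            "mode": "constant",
            "values": list(sources.values),
            "tdfs": list(sources.tdfs),
        }
    if isinstance(sources, BrownianSpec):
        return {
            "mode": "brownian",
            "initial_values": list(sources.initial_values),
            "step_variance": sources.step_variance,
            "n_candidates": sources.n_candidates,
            "n_keep": sources.n_keep,
            "min_separation": sources.min_separation,
            "tdfs": list(source_tdfs),
        }
    raise InvalidInputError(
        "only constant/brownian source specifications are serializable"
    )


def _turnover_to_dict(turnover: TurnoverSchedule):
    out = {"mode": turnover.mode}
    if turnover.lambda0 is not None:
        out["lambda0"] = turnover.lambda0
    if turnover.alpha is not None:
        out["alpha"] = turnover.alpha
    if turnover.table is not None:
        out["table"] = [list(row) for row in turnover.table]
    return out


def config_to_dict(config: ScenarioConfig) -> dict:
    if hasattr(config.diet, "proportions"):
        raise InvalidInputError(
            "only switch-frequency diets are serializable; concrete schedules "
            "should be written as proportion tables instead"
        )
    return {
        "horizon": config.horizon,
        "output_step": config.output_step,
        "initial_consumer": config.initial_consumer,
        "seed": config.seed,
        "sources": _sources_to_dict(config.sources, config.source_tdfs),
        "diet": {"omega": float(config.diet)},
        "turnover": _turnover_to_dict(config.turnover),
    }


def config_from_dict(data: dict) -> ScenarioConfig:
    src = dict(data["sources"])
    mode = src.pop("mode")
    tdfs = tuple(src.pop("tdfs", (1.0, 1.0)))
    if mode == "constant":
        sources = ConstantSourcesSpec(tuple(src["values"]), tdfs)
    elif mode == "brownian":
        sources = BrownianSpec(
            initial_values=tuple(src.get("initial_values", (0.0, 10.0))),
            step_variance=float(src.get("step_variance", 0.2)),
            n_candidates=int(src.get("n_candidates", 150)),
            n_keep=int(src.get("n_keep", 100)),
            min_separation=float(src.get("min_separation", 2.0)),
        )
    else:
        raise InvalidInputError(f"unknown sources mode {mode!r}")
    turnover_data = data["turnover"]
    turnover = make_turnover(
        turnover_data["mode"],
        lambda0=turnover_data.get("lambda0"),
        alpha=turnover_data.get("alpha"),
        table=turnover_data.get("table"),
    )
    return ScenarioConfig(
        sources=sources,
        turnover=turnover,
        diet=float(data["diet"]["omega"]),
        horizon=float(data.get("horizon", 500.0)),
        output_step=float(data.get("output_step", 1.0)),
        initial_consumer=(
            None
            if data.get("initial_consumer") is None
            else float(data["initial_consumer"])
        ),
        source_tdfs=tdfs,
        seed=int(data.get("seed", 0)),
    )


def load_config(path) -> ScenarioConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data)


def dump_config(config: ScenarioConfig, path):
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
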