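"""CSV/JSON readers and writers for sessions, traces, steps and filters.

All on-disk formats are plain text: wide CSV for time series (one row per
frame), one-row-per-step CSV for step tables, and JSON sidecars for
metadata (smoothing parameters, filter configs, fit parameters).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .filters import FilterConfig, LinearFilter
from .kinematics import TrackedSession
from .synthetic import CommandedBout, SimulationConfig
from .velocity import VelocityTraces

__all__ = [
    "write_session_csv",
    "read_session_csv",
    "write_traces_csv",
    "read_traces_csv",
    "write_step_table",
    "read_step_table",
    "write_filter",
    "read_filter",
    "write_bout_table",
    "load_config",
    "dump_config",
    "write_ground_truth",
]


def write_session_csv(session: TrackedSession, path) -> None:
    """One row per frame: time_s plus <keypoint>_x / <keypoint>_y columns."""
    cols = {"time_s": session.time}
    for name, arr in session.keypoints.items():
        cols[f"{name}_x"] = arr[:, 0]
        cols[f"{name}_y"] = arr[:, 1]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"coordinate_space": session.coordinate_space, "mode": session.mode}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_session_csv(path, mode: str = None, coordinate_space: str = None) -> TrackedSession:
    """Read a session CSV (or any generic time + named x/y keypoint table)."""
    df = pd.read_csv(path)
    sidecar = Path(str(path) + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    names = sorted({c[:-2] for c in df.columns if c.endswith("_x")})
    keypoints = {
        n: np.stack([df[f"{n}_x"].to_numpy(), df[f"{n}_y"].to_numpy()], axis=1) for n in names
    }
    return TrackedSession(
        time=df["time_s"].to_numpy(),
        keypoints=keypoints,
        coordinate_space=coordinate_space or meta.get("coordinate_space", "world_mm"),
        mode=mode or meta.get("mode", "free"),
    )


def write_traces_csv(traces: VelocityTraces, path) -> None:
    cols = {
        "time_s": traces.time,
        "rotational": traces.rotational,
        "forward": traces.forward,
        "lateral": traces.lateral,
    }
    for name in ("rotational_heavy", "forward_accel", "rotational_accel", "lateral_accel"):
        val = getattr(traces, name)
        if val is not None:
            cols[name] = val
    if traces.walking_mask is not None:
        cols["walking"] = traces.walking_mask.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
    Path(str(path) + ".json").write_text(json.dumps({"rate": traces.rate, **traces.meta}))


def read_traces_csv(path) -> VelocityTraces:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    rate = meta.pop("rate")
    get = lambda c: df[c].to_numpy() if c in df.columns else None
    mask = get("walking")
    return VelocityTraces(
        rate=rate,
        rotational=df["rotational"].to_numpy(),
        forward=df["forward"].to_numpy(),
        lateral=df["lateral"].to_numpy(),
        rotational_heavy=get("rotational_heavy"),
        forward_accel=get("forward_accel"),
        rotational_accel=get("rotational_accel"),
        lateral_accel=get("lateral_accel"),
        walking_mask=mask.astype(bool) if mask is not None else None,
        meta=meta,
    )


def write_step_table(steps: pd.DataFrame, path) -> None:
    steps.to_csv(path, index=False)


def read_step_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_filter(filt: LinearFilter, path) -> None:
    pd.DataFrame({"lag_s": filt.lags, "value": filt.values}).to_csv(path, index=False)
    meta = {
        "valid": bool(filt.valid),
        "peak_time": float(filt.peak_time) if filt.valid else None,
        "config": dataclasses.asdict(filt.config) if filt.config else None,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_filter(path) -> LinearFilter:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    cfg = FilterConfig(**meta["config"]) if meta.get("config") else None
    return LinearFilter(
        lags=df["lag_s"].to_numpy(),
        values=df["value"].to_numpy(),
        config=cfg,
        valid=meta.get("valid", True),
    )


def write_bout_table(bouts, path, deltas=None) -> None:
    """Bout table CSV plus a JSON summary of category counts."""
    rows = []
    for i, b in enumerate(bouts):
        row = {
            "peak_time": b.peak_time,
            "start_time": b.start_time,
            "end_time": b.end_time,
            "duration": b.duration,
            "peak_rot_velocity": b.peak_rot_velocity,
            "direction_original": b.direction_original,
            "forward_at_start": b.forward_at_start,
            "forward_at_peak": b.forward_at_peak,
            "category": b.category,
        }
        if deltas is not None:
            d = deltas[i]
            for leg, v in d.d_stride_length.items():
                row[f"d_stride_{leg}"] = v
            for leg, v in d.d_step_direction.items():
                row[f"d_direction_{leg}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    counts = {}
    for b in bouts:
        counts[b.category or "unclassified"] = counts.get(b.category or "unclassified", 0) + 1
    Path(str(path) + ".json").write_text(json.dumps({"n_bouts": len(bouts), "categories": counts}))


def dump_config(config: SimulationConfig, path) -> None:
    d = dataclasses.asdict(config)
    d["turn_schedule"] = [dataclasses.asdict(b) for b in config.turn_schedule]
    text = yaml.safe_dump(d, sort_keys=False)
    Path(path).write_text(text)


def load_config(path) -> SimulationConfig:
    """Load a SimulationConfig from YAML or JSON mirroring the field names."""
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    bouts = tuple(CommandedBout(**b) for b in d.pop("turn_schedule", []) or ())
    for key in ("bleach_taus", "bleach_amps"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return SimulationConfig(turn_schedule=bouts, **d)


def write_ground_truth(ground_truth: dict, path) -> None:
    """Ground-truth JSON: config, per-leg steps and realized bouts."""
    cfg = ground_truth["config"]
    d = dataclasses.asdict(cfg)
    d["turn_schedule"] = [dataclasses.asdict(b) for b in cfg.turn_schedule]
    out = {
        "config": d,
        "steps": {
            leg: [list(s) for s in steps] for leg, steps in ground_truth["steps"].items()
        },
        "bouts": ground_truth["bouts"],
        "neural_lag": ground_truth["neural_lag"],
    }
    Path(path).write_text(json.dumps(out))
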