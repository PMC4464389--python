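"""Delimited-text and JSON formats for profiles, batches and reports.

The domain has no standard file format for microprobe traces, so plain
comma-separated text with unit-suffixed headers is used throughout:

* profile: ``depth_um,o2_mg_l`` plus a sidecar ``<stem>.meta.json`` with
  ``{diameter_um, surface_depth_um, boundary_layer_start_um, hour,
  replicate}``;
* batch record: ``time_h,LOV_mg_l,X_g_l,LAC_g_l,N_g_l`` (missing columns
  allowed);
* radial solution: ``r_um,c_mg_per_l`` preceded by one ``#``-prefixed
  JSON header line carrying D_eff, c_surface, r_obs and r_anox.

Readers validate strictly and name the offending line on failure; writer
output round-trips losslessly through the readers.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .batch_rates import BatchTimeSeries
from .pellet_model import PelletSolution
from .profile_fitting import OxygenProfile, classify_points

__all__ = [
    "read_profile",
    "write_profile",
    "read_batch",
    "write_batch",
    "read_solution",
    "write_solution",
    "write_report",
]

_BATCH_COLUMNS = {"LOV_mg_l": "LOV", "X_g_l": "X", "LAC_g_l": "LAC", "N_g_l": "N"}


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def _read_numeric_csv(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise FormatError(f"{path}, line {line}: non-numeric value {df[col][bad.idxmax()]!r} in {col}")
        df[col] = coerced
    return df


def read_profile(path) -> OxygenProfile:
    """Read one probe trace and its sidecar metadata; classify points."""
    path = Path(path)
    df = _read_numeric_csv(path, ["depth_um", "o2_mg_l"])
    depth = df["depth_um"].to_numpy()
    conc = df["o2_mg_l"].to_numpy()
    steps = np.diff(depth)
    if (steps <= 0).any():
        line = int(np.argmax(steps <= 0)) + 3
        raise FormatError(f"{path}, line {line}: probe depths must be strictly increasing")
    if (conc < 0).any():
        line = int(np.argmax(conc < 0)) + 2
        raise FormatError(f"{path}, line {line}: negative concentration {conc.min()}")
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise FormatError(f"{path}: sidecar metadata {meta_path.name} not found")
    meta = json.loads(meta_path.read_text())
    return classify_points(
        depth,
        conc,
        surface_depth=meta["surface_depth_um"],
        boundary_layer_start=meta["boundary_layer_start_um"],
        diameter=meta["diameter_um"],
        hour=meta.get("hour", float("nan")),
        replicate=str(meta.get("replicate", "")),
    )


def write_profile(profile: OxygenProfile, path, boundary_layer_start: float | None = None) -> Path:
    """Write a trace as CSV plus its sidecar metadata JSON."""
    path = Path(path)
    pd.DataFrame(
        {"depth_um": profile.positions, "o2_mg_l": profile.concentrations}
    ).to_csv(path, index=False)
    if boundary_layer_start is None:
        bl = profile.positions[profile.mask("boundary_layer")]
        boundary_layer_start = float(bl[0]) if len(bl) else profile.surface_depth
    meta = {
        "diameter_um": profile.diameter,
        "surface_depth_um": profile.surface_depth,
        "boundary_layer_start_um": boundary_layer_start,
        "hour": None if np.isnan(profile.hour) else profile.hour,
        "replicate": profile.replicate,
    }
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_batch(path) -> BatchTimeSeries:
    """Read a batch concentration record (any analyte subset)."""
    path = Path(path)
    df = _read_numeric_csv(path, ["time_h"])
    t = df["time_h"].to_numpy()
    if (np.diff(t) <= 0).any():
        line = int(np.argmax(np.diff(t) <= 0)) + 3
        raise FormatError(f"{path}, line {line}: times must be strictly increasing")
    conc = {}
    for col, name in _BATCH_COLUMNS.items():
        if col in df.columns:
            values = df[col].to_numpy()
            if np.any(values[np.isfinite(values)] < 0):
                line = int(np.argmax(values < 0)) + 2
                raise FormatError(f"{path}, line {line}: negative concentration in {col}")
            conc[name] = values
    if not conc:
        raise FormatError(f"{path}: no analyte columns among {list(_BATCH_COLUMNS)}")
    return BatchTimeSeries(times=t, concentrations=conc)


def write_batch(series: BatchTimeSeries, path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_h": series.times})
    for col, name in _BATCH_COLUMNS.items():
        if name in series.concentrations:
            df[col] = series.concentrations[name]
    df.to_csv(path, index=False)
    return path


def write_solution(solution: PelletSolution, path) -> Path:
    """Radial field as r_um,c_mg_per_l with a JSON header comment line."""
    path = Path(path)
    header = {
        "D_eff_um2_s": solution.d_eff,
        "c_surface_mg_l": solution.c_surface,
        "r_obs_mg_l_s": solution.r_obs,
        "r_anox_um": solution.r_anox,
        "method": solution.method,
    }
    with path.open("w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.DataFrame({"r_um": solution.r, "c_mg_per_l": solution.c}).to_csv(fh, index=False)
    return path


def read_solution(path):
    """Return (header dict, DataFrame) written by :func:`write_solution`."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
    if not first.startswith("#"):
        raise FormatError(f"{path}: missing JSON header line")
    header = json.loads(first.lstrip("# "))
    df = _read_numeric_csv(path, ["r_um", "c_mg_per_l"])
    return header, df


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report(obj, path) -> Path:
    """Serialize a report object (dataclass, dict, ...) to JSON."""
    path = Path(path)
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    path.write_text(json.dumps(_jsonable(obj), indent=1) + "\n")
    return path
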