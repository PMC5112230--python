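"""CSV/JSON/YAML interfaces.

Trial-log CSV (one row per presentation, header mandatory, UTF-8, '.'
decimal): session_id, subject_id, trial_index, segment_id, block_index,
head_angle_deg, hemifield, deviation_deg, ray_angle_deg, response {left,
right, missed}, reaction_time_ms, onset_time_s.

Torsion CSV: time_s, left_deg, right_deg at a nominal 100 Hz.  The reader
tolerates gaps and drops rows with non-finite values, logging the counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import SchemaError
from .task import TRIAL_COLUMNS
from .torsion import TorsionTrace

__all__ = [
    "read_trial_log",
    "write_trial_log",
    "read_torsion_csv",
    "write_torsion_csv",
    "write_results_json",
    "write_series_csv",
    "load_cohort_config",
]

logger = logging.getLogger(__name__)

_NUMERIC_TRIAL_COLUMNS = (
    "trial_index",
    "segment_id",
    "block_index",
    "head_angle_deg",
    "deviation_deg",
    "ray_angle_deg",
    "onset_time_s",
)
_RESPONSES = {"left", "right", "missed"}


def read_trial_log(path) -> pd.DataFrame:
    """Read and validate a trial-log CSV."""
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise SchemaError(f"cannot parse trial log {path}: {err}")
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trial log {path} lacks column(s): {', '.join(missing)}")
    for col in _NUMERIC_TRIAL_COLUMNS:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based + header
            raise SchemaError(f"trial log {path}: non-numeric {col} at row {row}")
        df[col] = vals
    bad = ~df["response"].isin(_RESPONSES)
    if bad.any():
        row = int(df.index[bad][0]) + 2
        raise SchemaError(f"trial log {path}: invalid response at row {row}")
    answered = df["response"] != "missed"
    rt = pd.to_numeric(df["reaction_time_ms"], errors="coerce")
    if rt[answered].isna().any():
        row = int(df.index[answered & rt.isna()][0]) + 2
        raise SchemaError(f"trial log {path}: non-numeric reaction_time_ms at row {row}")
    df["reaction_time_ms"] = rt
    return df


def write_trial_log(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def read_torsion_csv(path) -> TorsionTrace:
    """Read a torsion CSV, dropping non-finite rows (counts logged)."""
    try:
        df = pd.read_csv(path)
    except Exception as err:
        raise SchemaError(f"cannot parse torsion trace {path}: {err}")
    missing = [c for c in ("time_s", "left_deg", "right_deg") if c not in df.columns]
    if missing:
        raise SchemaError(f"torsion trace {path} lacks column(s): {', '.join(missing)}")
    arr = df[["time_s", "left_deg", "right_deg"]].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(arr.to_numpy()).all(axis=1)
    dropped = int((~finite).sum())
    if dropped:
        logger.info("torsion trace %s: dropped %d non-finite row(s)", path, dropped)
    arr = arr[finite]
    if arr.empty:
        raise SchemaError(f"torsion trace {path} has no valid samples")
    t = arr["time_s"].to_numpy()
    if (np.diff(t) <= 0).any():
        raise SchemaError(f"torsion trace {path}: timestamps not strictly increasing")
    return TorsionTrace(
        time_s=t, left_deg=arr["left_deg"].to_numpy(), right_deg=arr["right_deg"].to_numpy()
    )


def write_torsion_csv(trace: TorsionTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.4f")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results_json(results: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(results), indent=2))


def write_series_csv(series: pd.DataFrame, path) -> None:
    series.to_csv(path, index=False, float_format="%.6f")


def load_cohort_config(path) -> "CohortConfig":
    """Cohort configuration from YAML (any subset of CohortConfig fields)."""
    from .cohort import CohortConfig

    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as err:
        raise SchemaError(f"cannot parse config {path}: {err}")
    if not isinstance(data, dict):
        raise SchemaError(f"config {path} must be a mapping")
    try:
        return CohortConfig.from_dict(data)
    except TypeError as err:
        raise SchemaError(f"config {path}: {err}")
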