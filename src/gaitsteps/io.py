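"""Readers and writers for the package's plain-text formats.

Raw recordings travel as CSV with header ``time,ax,ay,az`` (seconds and g,
'.' decimal); protocols and detector parameters as JSON; indirect-calorimetry
traces as CSV ``minute,vo2_ml_min,vco2_ml_min``; configuration as YAML.
Every writer's output is re-readable by the matching reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detector import DetectorParams
from .energy import ICTrace
from .protocol import ProtocolSpec
from .raw_signal import NonUniformSamplingError, TriaxialRecording

__all__ = [
    "read_raw_csv",
    "write_raw_csv",
    "read_protocol_json",
    "write_protocol_json",
    "read_params_json",
    "write_params_json",
    "read_ic_csv",
    "write_ic_csv",
    "load_yaml_config",
    "config_hash",
]

RAW_COLUMNS = ["time", "ax", "ay", "az"]


def read_raw_csv(path) -> TriaxialRecording:
    """Read a raw triaxial CSV; fs is inferred from the median time spacing.

    Errors carry the first offending data row (1-based, excluding header).
    """
    df = pd.read_csv(path)
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in RAW_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        nan_rows = np.nonzero(numeric.isna().to_numpy())[0]
        if nan_rows.size:
            raise ValueError(
                f"{path}: non-numeric value in column '{col}' at data row {nan_rows[0] + 1}"
            )
        df[col] = numeric
    t = df["time"].to_numpy(dtype=float)
    if len(t) < 1:
        raise ValueError(f"{path}: empty file")
    fs = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    try:
        return TriaxialRecording(t, df["ax"].to_numpy(), df["ay"].to_numpy(),
                                 df["az"].to_numpy(), fs)
    except NonUniformSamplingError as err:
        raise NonUniformSamplingError(f"{path}: {err}") from None


def write_raw_csv(rec: TriaxialRecording, path) -> None:
    pd.DataFrame({
        "time": rec.t, "ax": rec.ax, "ay": rec.ay, "az": rec.az
    }).to_csv(path, index=False, float_format="%.10g")


def read_protocol_json(path) -> ProtocolSpec:
    with open(path) as fh:
        return ProtocolSpec.from_dict(json.load(fh))


def write_protocol_json(protocol: ProtocolSpec, path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2) + "\n")


def read_params_json(path) -> DetectorParams:
    with open(path) as fh:
        return DetectorParams.from_dict(json.load(fh))


def write_params_json(params: DetectorParams, path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2) + "\n")


def read_ic_csv(path) -> ICTrace:
    df = pd.read_csv(path)
    for col in ("vo2_ml_min", "vco2_ml_min"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column '{col}'")
    return ICTrace(df["vo2_ml_min"].to_numpy(dtype=float),
                   df["vco2_ml_min"].to_numpy(dtype=float))


def write_ic_csv(trace: ICTrace, path) -> None:
    pd.DataFrame({
        "minute": np.arange(len(trace)),
        "vo2_ml_min": trace.vo2_ml_min,
        "vco2_ml_min": trace.vco2_ml_min,
    }).to_csv(path, index=False)


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def config_hash(config: dict) -> str:
    """Stable hash of a JSON-serialisable configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
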