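"""Delimited-text I/O for sensor streams, session manifests and variable tables.

Formats:

* sensor stream — CSV with header ``time_s,gx_dps,gy_dps,gz_dps,ax_g,ay_g,az_g``
  (gyro in deg/s, accelerometer in g), one file per sensor;
* session manifest — YAML naming horse id, surface, sample rate, standstill
  window and the placement -> file mapping;
* gait-variable table — CSV with header
  ``horse_id,surface,evaluator_id,evaluator_type,repetition,<19 variables>``;
* blinding key — CSV ``blinded_id,horse_id,copy``.
"""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd
import yaml

from .containers import PLACEMENTS, IMUSession, SensorStream, TABLE_META_COLUMNS, VARIABLE_COLUMNS
from .errors import ParameterError

STREAM_COLUMNS = ["time_s", "gx_dps", "gy_dps", "gz_dps", "ax_g", "ay_g", "az_g"]


def write_stream_csv(stream: SensorStream, path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.times, stream.gyro, stream.accel]), columns=STREAM_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_stream_csv(path, placement: str, sample_rate: float) -> SensorStream:
    df = pd.read_csv(path)
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ParameterError(f"stream file {path} missing columns {missing}")
    gyro = df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy()
    accel = df[["ax_g", "ay_g", "az_g"]].to_numpy()
    return SensorStream(placement, sample_rate, gyro, accel)


def write_session(session: IMUSession, out_dir, name: str | None = None) -> pathlib.Path:
    """Write six stream files plus a YAML manifest; returns the manifest path."""
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    name = name or f"{session.horse_id}_{session.surface}"
    files = {}
    for placement in PLACEMENTS:
        fname = f"{name}_{placement}.csv"
        write_stream_csv(session.streams[placement], out_dir / fname)
        files[placement] = fname
    manifest = {
        "horse_id": session.horse_id,
        "surface": session.surface,
        "sample_rate_hz": session.sample_rate,
        "standstill_window": [int(session.standstill_window[0]), int(session.standstill_window[1])],
        "streams": files,
    }
    path = out_dir / f"{name}_manifest.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


def read_session(manifest_path) -> IMUSession:
    manifest_path = pathlib.Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    fs = float(manifest["sample_rate_hz"])
    streams = {
        placement: read_stream_csv(manifest_path.parent / fname, placement, fs)
        for placement, fname in manifest["streams"].items()
    }
    return IMUSession(
        horse_id=str(manifest["horse_id"]),
        surface=str(manifest["surface"]),
        streams=streams,
        standstill_window=tuple(manifest["standstill_window"]),
    )


def write_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in TABLE_META_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False, float_format="%.9g")


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("horse_id", "evaluator_id", "repetition"):
        if col not in df.columns:
            raise ParameterError(f"table {path} missing column {col!r}")
    if "surface" not in df.columns:
        df["surface"] = "unspecified"
    return df


def write_blinding_key(key: dict, path) -> None:
    rows = [
        {"blinded_id": bid, "horse_id": horse, "copy": copy}
        for bid, (horse, copy) in sorted(key.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_blinding_key(path) -> dict:
    df = pd.read_csv(path)
    return {str(r.blinded_id): (str(r.horse_id), int(r.copy)) for r in df.itertuples()}
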