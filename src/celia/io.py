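"""File formats: long-format trace CSV, observables CSV, calibration I/O.

The shared trace schema is long-format CSV with columns
``well_id, time_min, series_type, name, value`` where series_type is
"species" or "channel".  Floats are written with ``repr`` precision, so a
round-trip through CSV is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .network import ValidationError
from .quantify import CalibrationModel
from .simulate import TraceSet
from .traces import Trace

__all__ = [
    "traceset_to_frame",
    "frame_to_traces",
    "write_traces",
    "read_traces",
    "write_calibration",
    "read_calibration",
]

TRACE_COLUMNS = ["well_id", "time_min", "series_type", "name", "value"]


def traceset_to_frame(ts: TraceSet, well_id: str = "well", include_species: bool = True) -> pd.DataFrame:
    """Flatten a TraceSet to the long-format schema."""
    rows = []
    if include_species:
        for name, vals in ts.concentrations.items():
            rows.append(
                pd.DataFrame(
                    {
                        "well_id": well_id,
                        "time_min": ts.times,
                        "series_type": "species",
                        "name": name,
                        "value": vals,
                    }
                )
            )
    for name, vals in ts.channels.items():
        rows.append(
            pd.DataFrame(
                {
                    "well_id": well_id,
                    "time_min": ts.times,
                    "series_type": "channel",
                    "name": name,
                    "value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def traces_to_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    rows = [
        pd.DataFrame(
            {
                "well_id": tr.well_id,
                "time_min": tr.times,
                "series_type": "channel",
                "name": tr.channel,
                "value": tr.values,
            }
        )
        for tr in traces
    ]
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[Trace]:
    """Channel traces from a long-format frame (species rows are ignored)."""
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError("columns", f"trace CSV missing columns {sorted(missing)}")
    chan = df[df["series_type"] == "channel"]
    traces = []
    for (well_id, name), grp in chan.groupby(["well_id", "name"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            Trace(
                times=grp["time_min"].to_numpy(float),
                values=grp["value"].to_numpy(float),
                channel=str(name),
                well_id=str(well_id),
            )
        )
    return traces


def write_traces(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)  # pandas writes repr-precision floats


def read_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError("columns", f"{path}: missing columns {sorted(missing)}")
    return df


def write_calibration(model: CalibrationModel, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(model.to_dict(), indent=2, sort_keys=True) + "\n")


def read_calibration(path: str | Path) -> CalibrationModel:
    return CalibrationModel.from_dict(json.loads(Path(path).read_text()))
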