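"""Plain-text serialization: TSV tables and YAML/JSON configuration."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .containers import ROWS, IntensityTrace, StateLattice

TRACE_COLUMNS = ["cell_id", "row", "position", "frame", "red", "green"]


def write_traces(traces: Iterable[IntensityTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "row": tr.row,
                    "position": tr.position,
                    "frame": np.arange(len(tr)),
                    "red": tr.red,
                    "green": tr.green,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path: str | Path, dt: float = 2.5) -> list[IntensityTrace]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace table lacks columns: {sorted(missing)}")
    traces = []
    for (cell_id, row, position), grp in df.groupby(
        ["cell_id", "row", "position"], sort=True
    ):
        grp = grp.sort_values("frame")
        traces.append(
            IntensityTrace(
                cell_id=str(cell_id),
                row=str(row),
                position=int(position),
                red=grp["red"].to_numpy(float),
                green=grp["green"].to_numpy(float),
                dt=dt,
            )
        )
    return traces


def write_lattice(lattice: StateLattice, path: str | Path) -> None:
    lattice.to_frame().to_csv(path, sep="\t", index=False)


def read_lattice(path: str | Path, dt: float = 2.5) -> StateLattice:
    return StateLattice.from_frame(pd.read_csv(path, sep="\t"), dt=dt)


def write_transitions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_transitions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["entry_frame"] = df["entry_frame"].astype("Int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_intervals(intervals, path: str | Path) -> None:
    pd.DataFrame({"interval_frames": np.asarray(intervals, dtype=int)}).to_csv(
        path, sep="\t", index=False
    )


def read_intervals(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t")["interval_frames"].to_numpy(int)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
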