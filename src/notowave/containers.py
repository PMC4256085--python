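"""Core in-memory containers shared across the analysis stages.

The notochord is observed in mid-sagittal section as two anterior→posterior
columns of cells (``upper`` = dorsal, ``lower`` = ventral).  All stages work
on one of three representations:

* :class:`IntensityTrace` — one cell's red/green Fucci intensities per frame;
* :class:`StateLattice` — two rows × n positions × T frames of binary G1/S
  states (once S, always S);
* a *transition table* — a tidy :class:`pandas.DataFrame` with columns
  ``row``, ``position``, ``entry_frame`` (nullable Int64; NA = censored,
  i.e. the cell was never seen to enter S phase).

Positions are 1-based, anterior→posterior.  Frames are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ROWS = ("upper", "lower")

#: schema of a transition table
TRANSITION_COLUMNS = ("row", "position", "entry_frame")


@dataclass
class IntensityTrace:
    """Red/green Fucci intensity time series of a single cell."""

    cell_id: str
    row: str
    position: int
    red: np.ndarray
    green: np.ndarray
    dt: float = 2.5

    def __post_init__(self) -> None:
        self.red = np.asarray(self.red, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if self.row not in ROWS:
            raise ValueError(f"row must be one of {ROWS}, got {self.row!r}")
        if self.red.ndim != 1 or self.green.ndim != 1:
            raise ValueError("red and green must be 1-D arrays")
        if len(self.red) != len(self.green) or len(self.red) < 1:
            raise ValueError("red and green must have equal length >= 1")
        if (self.red < 0).any() or (self.green < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __len__(self) -> int:
        return len(self.red)


@dataclass
class StateLattice:
    """Binary G1/S states on the two-row cell lattice.

    ``states`` has shape (2, n_cells, t_max) with axis 0 ordered as
    ``("upper", "lower")``; True = S phase.  Per-cell state sequences must be
    monotone (no S→G1 reversion), which is checked at construction.
    """

    states: np.ndarray
    dt: float = 2.5

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=bool)
        if self.states.ndim != 3 or self.states.shape[0] != len(ROWS):
            raise ValueError(
                f"states must have shape (2, n_cells, t_max), got {self.states.shape}"
            )
        if self.states.shape[2] >= 2:
            diffs = self.states[:, :, 1:].astype(int) - self.states[:, :, :-1].astype(int)
            if (diffs < 0).any():
                raise ValueError("state sequences must be monotone (no S->G1 reversion)")

    @property
    def n_cells(self) -> int:
        return self.states.shape[1]

    @property
    def t_max(self) -> int:
        return self.states.shape[2]

    def row(self, name: str) -> np.ndarray:
        """Return one row's (n_cells, t_max) state array."""
        return self.states[ROWS.index(name)]

    @classmethod
    def from_rows(cls, upper: np.ndarray, lower: np.ndarray, dt: float = 2.5) -> "StateLattice":
        upper = np.asarray(upper, dtype=bool)
        lower = np.asarray(lower, dtype=bool)
        if upper.shape != lower.shape:
            raise ValueError("upper and lower rows must have identical shape")
        return cls(states=np.stack([upper, lower]), dt=dt)

    def entry_frames(self) -> pd.DataFrame:
        """First S frame per cell as a transition table (NA if never S)."""
        records = []
        for r, name in enumerate(ROWS):
            ever = self.states[r].any(axis=1)
            first = np.argmax(self.states[r], axis=1)
            for i in range(self.n_cells):
                records.append(
                    {
                        "row": name,
                        "position": i + 1,
                        "entry_frame": int(first[i]) if ever[i] else pd.NA,
                    }
                )
        df = pd.DataFrame.from_records(records)
        df["entry_frame"] = df["entry_frame"].astype("Int64")
        return df

    def to_frame(self) -> pd.DataFrame:
        """Tidy long format: row, position, frame, state (0=G1, 1=S)."""
        r, i, t = np.meshgrid(
            np.arange(2), np.arange(1, self.n_cells + 1), np.arange(self.t_max), indexing="ij"
        )
        return pd.DataFrame(
            {
                "row": np.asarray(ROWS)[r.ravel()],
                "position": i.ravel(),
                "frame": t.ravel(),
                "state": self.states.ravel().astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, dt: float = 2.5) -> "StateLattice":
        """Rebuild a lattice from the tidy long format written by :meth:`to_frame`."""
        n = int(df["position"].max())
        t_max = int(df["frame"].max()) + 1
        states = np.zeros((2, n, t_max), dtype=bool)
        seen = np.zeros((2, n, t_max), dtype=bool)
        r_idx = df["row"].map({name: k for k, name in enumerate(ROWS)}).to_numpy()
        if np.isnan(r_idx.astype(float)).any():
            raise ValueError(f"rows must be in {ROWS}")
        i_idx = df["position"].to_numpy(int) - 1
        t_idx = df["frame"].to_numpy(int)
        states[r_idx, i_idx, t_idx] = df["state"].to_numpy(int).astype(bool)
        seen[r_idx, i_idx, t_idx] = True
        if not seen.all():
            raise ValueError("lattice table does not cover the full (row, position, frame) grid")
        return cls(states=states, dt=dt)


def make_transition_table(
    entries: Mapping[str, Sequence], dt: float | None = None
) -> pd.DataFrame:
    """Build a transition table from per-row entry-frame sequences.

    ``entries`` maps row name -> sequence of entry frames (``None``/NaN for
    censored cells), position 1..len(seq).
    """
    records = []
    for row, seq in entries.items():
        if row not in ROWS:
            raise ValueError(f"row must be one of {ROWS}, got {row!r}")
        for i, e in enumerate(seq, start=1):
            censored = e is None or (isinstance(e, float) and np.isnan(e)) or e is pd.NA
            records.append(
                {"row": row, "position": i, "entry_frame": pd.NA if censored else int(e)}
            )
    df = pd.DataFrame.from_records(records)
    df["entry_frame"] = df["entry_frame"].astype("Int64")
    return df


@dataclass
class IntervalDistribution:
    """Normalized probability mass over integer waiting times (frames).

    ``n_obs`` is the number of raw intervals behind the distribution; it is
    needed for pseudo-count regularization when the distribution stands on
    the simulation side of a Kullback-Leibler comparison.
    """

    pmf: pd.Series
    n_obs: int
    dt: float = 2.5

    def __post_init__(self) -> None:
        self.pmf = pd.Series(self.pmf, dtype=float).sort_index()
        if (self.pmf < 0).any():
            raise ValueError("pmf values must be non-negative")
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError(f"pmf must sum to 1, got {self.pmf.sum()!r}")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")

    @property
    def support(self) -> np.ndarray:
        return self.pmf.index.to_numpy(int)

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[int], dt: float = 2.5
    ) -> "IntervalDistribution":
        vals = np.asarray(list(intervals), dtype=int)
        if vals.size == 0:
            raise ValueError("cannot build a distribution from an empty interval list")
        counts = pd.Series(vals).value_counts().sort_index()
        return cls(pmf=counts / counts.sum(), n_obs=int(vals.size), dt=dt)

    def mean_minutes(self) -> float:
        return float((self.pmf.index.to_numpy(float) * self.pmf.to_numpy()).sum() * self.dt)
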