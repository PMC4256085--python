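"""Spatial statistics of the G1/S transition window.

Two landmarks bracket the mixed red/green region of each notochord row:

* PGC — posterior-most green cell, the largest position in S phase;
* ARC — anterior-most red cell, the smallest position still in G1.

The *transition window* is operationally the PGC plus the ``window-1`` cells
anterior to it (8 cells by default, one somite width).  The waiting times
between successive PGC advance events are the interval statistic that feeds
model selection.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import ROWS, IntervalDistribution, StateLattice

DEFAULT_WINDOW = 8


def find_pgc(row_states: np.ndarray, t: int) -> Optional[int]:
    """Posterior-most S cell (1-based position) in a row at frame t, or None."""
    col = _column(row_states, t)
    idx = np.flatnonzero(col)
    return int(idx[-1]) + 1 if idx.size else None


def find_arc(row_states: np.ndarray, t: int) -> Optional[int]:
    """Anterior-most G1 cell (1-based position) in a row at frame t, or None."""
    col = _column(row_states, t)
    idx = np.flatnonzero(~col)
    return int(idx[0]) + 1 if idx.size else None


def _column(row_states: np.ndarray, t: int) -> np.ndarray:
    row_states = np.asarray(row_states, dtype=bool)
    if row_states.ndim != 2:
        raise ValueError("row_states must be a 2-D (n_cells, t_max) array")
    if not (0 <= t < row_states.shape[1]):
        raise ValueError(f"frame {t} outside [0, {row_states.shape[1]})")
    return row_states[:, t]


def pgc_series(row_states: np.ndarray) -> np.ndarray:
    """PGC position per frame (nan where no S cell exists)."""
    row_states = np.asarray(row_states, dtype=bool)
    n = row_states.shape[0]
    any_s = row_states.any(axis=0)
    pos = n - np.argmax(row_states[::-1, :], axis=0)
    return np.where(any_s, pos, np.nan).astype(float)


def arc_series(row_states: np.ndarray) -> np.ndarray:
    """ARC position per frame (nan once every cell is S)."""
    row_states = np.asarray(row_states, dtype=bool)
    all_s = row_states.all(axis=0)
    pos = np.argmax(~row_states, axis=0) + 1
    return np.where(all_s, np.nan, pos).astype(float)


def window_green_count(
    row_states: np.ndarray, t: int, window: int = DEFAULT_WINDOW
) -> Optional[int]:
    """Number of S cells in the window [PGC-window+1, PGC] of one row.

    The window is clipped at the anterior boundary while the PGC is within
    the first ``window`` positions.  Returns None when the row has no PGC.
    """
    pgc = find_pgc(row_states, t)
    if pgc is None:
        return None
    lo = max(1, pgc - window + 1)
    return int(np.asarray(row_states, dtype=bool)[lo - 1 : pgc, t].sum())


def pair_count(
    lattice: StateLattice,
    t: int,
    window: int = DEFAULT_WINDOW,
    landmark: str = "lower",
) -> Optional[int]:
    """Positions in the landmark-row window where BOTH rows are green.

    The window is anchored at the landmark row's PGC (the lower row by
    convention).  Returns None when the landmark row has no PGC.
    """
    if landmark not in ROWS:
        raise ValueError(f"landmark must be one of {ROWS}, got {landmark!r}")
    pgc = find_pgc(lattice.row(landmark), t)
    if pgc is None:
        return None
    lo = max(1, pgc - window + 1)
    both = lattice.row("upper")[lo - 1 : pgc, t] & lattice.row("lower")[lo - 1 : pgc, t]
    return int(both.sum())


def totals(lattice: StateLattice, t: int) -> dict[str, tuple[int, int]]:
    """Per-row (n_G1, n_S) cell counts at frame t."""
    out = {}
    for row in ROWS:
        col = _column(lattice.row(row), t)
        n_s = int(col.sum())
        out[row] = (lattice.n_cells - n_s, n_s)
    return out


def totals_series(lattice: StateLattice) -> pd.DataFrame:
    """Tidy per-frame totals: frame, row, n_G1, n_S."""
    records = []
    for row in ROWS:
        n_s = lattice.row(row).sum(axis=0)
        for t in range(lattice.t_max):
            records.append(
                {"frame": t, "row": row, "n_G1": lattice.n_cells - int(n_s[t]), "n_S": int(n_s[t])}
            )
    return pd.DataFrame.from_records(records)


def landmark_intervals(row_states: np.ndarray, landmark: str = "pgc") -> np.ndarray:
    """Waiting times (frames) between successive landmark advance events.

    An advance event is a frame at which the landmark position strictly
    increases; the first appearance of the landmark starts the clock without
    contributing an interval.  A jump of several cells counts as one event.
    """
    if landmark == "pgc":
        series = pgc_series(row_states)
    elif landmark == "arc":
        series = arc_series(row_states)
    else:
        raise ValueError(f"landmark must be 'pgc' or 'arc', got {landmark!r}")
    intervals: list[int] = []
    last_t: Optional[int] = None
    prev: Optional[float] = None
    for t, v in enumerate(series):
        if np.isnan(v):
            continue
        if prev is None:
            prev, last_t = v, t
        elif v > prev:
            intervals.append(t - last_t)
            prev, last_t = v, t
    return np.asarray(intervals, dtype=int)


def pooled_intervals(
    lattice: StateLattice, landmark: str = "pgc"
) -> np.ndarray:
    """Upper + lower row intervals concatenated (the per-replicate pooling)."""
    return np.concatenate(
        [landmark_intervals(lattice.row(row), landmark) for row in ROWS]
    )


def interval_distribution(
    intervals: Iterable[int], dt: float = 2.5
) -> IntervalDistribution:
    """Normalized pmf of integer-frame waiting times (1-frame bins)."""
    return IntervalDistribution.from_intervals(intervals, dt=dt)


def window_series(
    lattice: StateLattice,
    window: int = DEFAULT_WINDOW,
    landmark: str = "lower",
) -> pd.DataFrame:
    """Per-frame, per-row landmark positions and window counts.

    Columns: frame, row, pgc, arc, green_count, pair_count, clipped.
    ``pair_count`` (anchored at the landmark row's PGC) is repeated on both
    rows of a frame; ``clipped`` flags frames whose window was truncated at
    the anterior boundary.
    """
    records = []
    for t in range(lattice.t_max):
        pc = pair_count(lattice, t, window=window, landmark=landmark)
        for row in ROWS:
            rs = lattice.row(row)
            pgc = find_pgc(rs, t)
            records.append(
                {
                    "frame": t,
                    "row": row,
                    "pgc": pgc,
                    "arc": find_arc(rs, t),
                    "green_count": window_green_count(rs, t, window=window),
                    "pair_count": pc,
                    "clipped": (pgc is not None and pgc < window),
                }
            )
    df = pd.DataFrame.from_records(records)
    for col in ("pgc", "arc", "green_count", "pair_count"):
        df[col] = df[col].astype("Int64")
    return df
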