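"""G1/S transition calling from dual-channel Fucci intensity traces.

A cell is called as having entered S phase at the first frame of a run of
``persistence`` (default 5) consecutive frames in which the green (S/G2/M)
signal strictly exceeds the red (G1) signal.  Ties break the run, and the run
must fit entirely within the trace — a green-dominant tail shorter than
``persistence`` frames leaves the cell censored.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .containers import ROWS, IntensityTrace, StateLattice, make_transition_table

DEFAULT_PERSISTENCE = 5


def call_transition(
    trace: IntensityTrace, persistence: int = DEFAULT_PERSISTENCE
) -> Optional[int]:
    """Return the S-entry frame of one trace, or None if censored.

    The entry frame is the *first* frame of the persistence run, i.e. the
    crossing frame of the red and green curves.
    """
    if persistence < 1:
        raise ValueError(f"persistence must be >= 1, got {persistence}")
    if not isinstance(trace, IntensityTrace):
        raise TypeError("trace must be an IntensityTrace")
    mask = trace.green > trace.red  # strict: ties break the run
    if len(mask) < persistence:
        return None
    runs = sliding_window_view(mask, persistence).all(axis=1)
    if not runs.any():
        return None
    return int(np.argmax(runs))


def binarize(
    traces: Iterable[IntensityTrace], persistence: int = DEFAULT_PERSISTENCE
) -> tuple[StateLattice, pd.DataFrame]:
    """Call every trace and assemble the binary state lattice.

    The traces must tile a full rectangular (row × position × frame) grid over
    both notochord rows; duplicates or gaps are rejected.  State is S from the
    called entry frame onward, so monotonicity holds by construction.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    lengths = {len(tr) for tr in traces}
    if len(lengths) != 1:
        raise ValueError(f"traces have unequal lengths: {sorted(lengths)}")
    t_max = lengths.pop()
    dt = traces[0].dt

    seen: dict[tuple[str, int], IntensityTrace] = {}
    for tr in traces:
        key = (tr.row, tr.position)
        if key in seen:
            raise ValueError(f"duplicate trace for (row, position) = {key}")
        seen[key] = tr
    n = max(pos for _, pos in seen)
    gaps = [
        (row, pos) for row in ROWS for pos in range(1, n + 1) if (row, pos) not in seen
    ]
    if gaps:
        raise ValueError(f"traces do not cover the full grid; missing cells: {gaps}")

    entries = {
        row: [call_transition(seen[(row, pos)], persistence) for pos in range(1, n + 1)]
        for row in ROWS
    }
    table = make_transition_table(entries)

    frames = np.arange(t_max)
    states = np.zeros((2, n, t_max), dtype=bool)
    for r, row in enumerate(ROWS):
        for i, e in enumerate(entries[row]):
            if e is not None:
                states[r, i] = frames >= e
    return StateLattice(states=states, dt=dt), table
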