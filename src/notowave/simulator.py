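"""Markov lattice model of the stochastic G1/S transition.

A regulatory wave travels anterior→posterior over a 1-D lattice of cells.
The wave advances in steps of ``z`` cells at times ``t_k = k·L_c·z/(λ·Δt)``
(frame units, k = 1, 2, ...), so cell ``i`` becomes *licensed* once the front
``z·#{k : t_k ≤ t}`` has reached it.  Every licensed cell that is still in G1
enters S phase independently with probability ``αΔt`` per frame; there is no
backward transition.  ``z=1`` is the continuous wave; ``z=8`` steps one somite
width per segmentation-clock cycle (30 min); ``z=16``/``z=24`` are the two-
and three-fold periodic modes with 60/90-min recurrence.

Rather than looping Bernoulli coin flips frame by frame, :func:`run` draws
each cell's post-licensing waiting time directly from the geometric
distribution with success probability ``αΔt`` — cells are independent, so the
two schemes are identical in distribution, and vectorized sampling keeps the
repeated simulations of the model-selection stage cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig
from .containers import ROWS, StateLattice, make_transition_table

_EPS = 1e-9  # guards float comparisons on the t_k grid

#: candidate step sizes for the standard 8-cell somite width
CANDIDATES_8CELL = (1, 8, 16, 24)
#: sensitivity candidates when a somite is taken as 7 cells wide
CANDIDATES_7CELL = (1, 7, 14, 21)


@dataclass(frozen=True)
class SignalWave:
    """Schedule of the traveling licensing wave.

    The front position after frame ``t`` is ``z·#{k ≥ 1 : t_k ≤ t}`` cells;
    with ``from_k0`` the count starts at k=0 and the first ``z`` cells are
    licensed from frame 0.
    """

    z: int
    step_frames: float
    from_k0: bool = False

    @classmethod
    def from_config(cls, config: ModelConfig) -> "SignalWave":
        return cls(
            z=config.z,
            step_frames=config.step_interval_frames,
            from_k0=config.license_from_k0,
        )

    def n_steps(self, t: float) -> int:
        """Number of wave steps fired by frame t (k ≥ 1 count)."""
        if t < 0:
            raise ValueError(f"t must be >= 0, got {t}")
        base = int(math.floor((t + _EPS) / self.step_frames))
        return base + (1 if self.from_k0 else 0)

    def front(self, t: float) -> int:
        """Posterior-most licensed position at frame t (0 if none)."""
        return self.z * self.n_steps(t)

    def license_frame(self, i: int) -> int:
        """Earliest integer frame at which position i is licensed."""
        if i < 1:
            raise ValueError(f"position must be >= 1, got {i}")
        k = math.ceil(i / self.z)
        if self.from_k0:
            k -= 1
        return int(math.ceil(k * self.step_frames - _EPS))


def signal_arrived(i: int, t: float, wave: SignalWave, n_cells: int | None = None) -> bool:
    """True iff the licensing condition f(i,t) ≤ 0 holds, with
    f(i,t) = i − z·#{k ≥ 1 : t_k ≤ t}."""
    if i < 1 or (n_cells is not None and i > n_cells):
        raise ValueError(f"position {i} outside the lattice")
    return i <= wave.front(t)


def run(
    config: ModelConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one lattice row.

    Returns
    -------
    states:
        (n_cells, t_max) boolean array, True = S phase.  All cells are G1 at
        frame 0; a cell licensed at frame ``lic`` can first be S at frame
        ``max(lic, 1)``.
    entry:
        float array of S-entry frames, ``nan`` where the cell never enters S
        within ``t_max`` (censored).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wave = SignalWave.from_config(config)
    n, T = config.n_cells, config.t_max

    lic = np.array([wave.license_frame(i) for i in range(1, n + 1)])
    first_chance = np.maximum(lic, 1)  # frame 0 is all-G1 by definition
    waits = rng.geometric(config.alpha_dt, size=n)  # trials incl. the success
    entry = first_chance + waits - 1
    censored = entry >= T

    frames = np.arange(T)
    states = frames[None, :] >= entry[:, None]
    states[censored, :] = False

    entry_out = entry.astype(float)
    entry_out[censored] = np.nan
    return states, entry_out


def run_pair(
    config: ModelConfig, seed_seq: np.random.SeedSequence | None = None
) -> tuple[StateLattice, pd.DataFrame]:
    """Two independent rows (upper/lower) sharing one wave schedule.

    Returns the packed :class:`StateLattice` and the truth transition table.
    """
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(config.seed)
    children = seed_seq.spawn(len(ROWS))
    rows, entries = {}, {}
    for name, child in zip(ROWS, children):
        states, entry = run(config, rng=np.random.default_rng(child))
        rows[name] = states
        entries[name] = entry
    lattice = StateLattice.from_rows(rows["upper"], rows["lower"], dt=config.dt)
    table = make_transition_table(entries)
    return lattice, table
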