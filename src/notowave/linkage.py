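"""Independence test of S-phase entry between the upper and lower rows.

The observed number of green *pairs* in the transition window is compared
with Monte-Carlo expectations under two in-silico nulls that keep each row's
observed green count:

* **random** — both rows' greens are placed uniformly at random on distinct
  window sites (independent rows);
* **biased** — the upper row is placed at random; lower greens are then laid
  down one at a time: a uniformly chosen still-red lower site turns green
  with probability ``q`` (default 0.9) when its upper partner is green and
  ``1-q`` otherwise, until the observed lower count is reached (positively
  coupled rows for q > 0.5).

Under the random null the expected pair count has the closed form
``g_upper·g_lower/window``, which the Monte-Carlo estimate must reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_REPS = 10_000
DEFAULT_Q = 0.9
DEFAULT_WINDOW = 8


@dataclass(frozen=True)
class NullSpec:
    """Configuration of an in-silico null for the pair-count statistic."""

    mode: str = "random"
    q: float = DEFAULT_Q
    reps: int = DEFAULT_REPS
    window: int = DEFAULT_WINDOW
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("random", "biased"):
            raise ValueError(f"mode must be 'random' or 'biased', got {self.mode!r}")
        if not (0.0 <= self.q <= 1.0):
            raise ValueError(f"q must be in [0, 1], got {self.q}")
        if self.reps < 1:
            raise ValueError(f"reps must be >= 1, got {self.reps}")
        if self.window < 1:
            raise ValueError(f"window must be >= 1, got {self.window}")


def _random_masks(g: int, window: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """(reps, window) boolean masks with exactly g uniformly random greens."""
    order = np.argsort(rng.random((reps, window)), axis=1)
    masks = np.zeros((reps, window), dtype=bool)
    rows = np.repeat(np.arange(reps), g)
    masks[rows, order[:, :g].ravel()] = True
    return masks


def _biased_masks(
    upper: np.ndarray, g_lower: int, q: float, rng: np.random.Generator
) -> np.ndarray:
    """Sequential biased placement of lower greens given upper masks.

    Implements the literal scheme: repeatedly pick a uniformly random
    still-red lower site; it turns green with probability q (upper partner
    green) or 1-q (upper partner red); stop once g_lower greens are placed.
    """
    reps, window = upper.shape
    lower = np.zeros((reps, window), dtype=bool)
    placed = np.zeros(reps, dtype=int)
    active = placed < g_lower
    while active.any():
        idx = np.flatnonzero(active)
        red = ~lower[idx]
        n_red = red.sum(axis=1)
        pick = (rng.random(idx.size) * n_red).astype(int)  # pick-th red site
        cum = np.cumsum(red, axis=1)
        site = np.argmax(cum == (pick + 1)[:, None], axis=1)
        p_flip = np.where(upper[idx, site], q, 1.0 - q)
        success = rng.random(idx.size) < p_flip
        lower[idx[success], site[success]] = True
        placed[idx[success]] += 1
        active = placed < g_lower
    return lower


def null_pair_expectation(g_upper: int, g_lower: int, spec: NullSpec) -> float:
    """Monte-Carlo expected pair count given the two rows' green counts."""
    w = spec.window
    for name, g in (("g_upper", g_upper), ("g_lower", g_lower)):
        if not (0 <= g <= w):
            raise ValueError(f"{name} must be in [0, {w}], got {g}")
    if g_upper == 0 or g_lower == 0:
        return 0.0
    rng = np.random.default_rng(spec.seed)
    upper = _random_masks(g_upper, w, spec.reps, rng)
    if spec.mode == "random":
        lower = _random_masks(g_lower, w, spec.reps, rng)
    else:
        lower = _biased_masks(upper, g_lower, spec.q, rng)
    return float((upper & lower).sum(axis=1).mean())


def linkage_curves(window_series: pd.DataFrame, spec: NullSpec) -> pd.DataFrame:
    """Observed pair counts alongside random- and biased-null expectations.

    ``window_series`` is the tidy frame produced by
    :func:`notowave.scoring.window_series`.  Frames where either row lacks a
    green count or the landmark PGC is missing are flagged and skipped.
    Columns: frame, observed, g_upper, g_lower, random_null, biased_null,
    skipped.
    """
    wide = window_series.pivot(index="frame", columns="row", values="green_count")
    pair = window_series.groupby("frame")["pair_count"].first()
    ss = np.random.SeedSequence(spec.seed)
    records = []
    for frame in wide.index:
        g_u, g_l = wide.loc[frame, "upper"], wide.loc[frame, "lower"]
        obs = pair.loc[frame]
        if pd.isna(g_u) or pd.isna(g_l) or pd.isna(obs):
            records.append(
                {"frame": int(frame), "observed": pd.NA, "g_upper": pd.NA,
                 "g_lower": pd.NA, "random_null": np.nan, "biased_null": np.nan,
                 "skipped": True}
            )
            continue
        s1, s2 = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2))
        rnd = null_pair_expectation(
            int(g_u), int(g_l),
            NullSpec("random", spec.q, spec.reps, spec.window, seed=s1),
        )
        bias = null_pair_expectation(
            int(g_u), int(g_l),
            NullSpec("biased", spec.q, spec.reps, spec.window, seed=s2),
        )
        records.append(
            {"frame": int(frame), "observed": int(obs), "g_upper": int(g_u),
             "g_lower": int(g_l), "random_null": rnd, "biased_null": bias,
             "skipped": False}
        )
    df = pd.DataFrame.from_records(records)
    for col in ("observed", "g_upper", "g_lower"):
        df[col] = df[col].astype("Int64")
    return df
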