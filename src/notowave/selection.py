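"""Kullback-Leibler model selection among candidate wave modes.

The data's PGC waiting-time distribution p(x) is compared with the interval
distribution q(x) of repeated simulations of each candidate step size z.
For every candidate, D(p, q) = Σ p(x)·ln(p(x)/q(x)) is computed over many
independent simulation replicates (300 by default) and candidates are ranked
by mean KL distance; pairwise two-sample Kolmogorov-Smirnov tests quantify
the separation between the KL samples of different candidates.

q(x) is an empirical simulation pmf and may miss support points that carry
experimental mass; before taking the ratio, q is regularized with a
pseudo-count ε = 1/(N_q + S) per union-support point (N_q simulated
intervals, S support size), which keeps D finite and non-negative without
noticeably distorting well-populated bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, pearsonr

from .config import ModelConfig
from .containers import ROWS, IntervalDistribution, StateLattice
from .scoring import pooled_intervals, window_green_count
from .simulator import CANDIDATES_7CELL, CANDIDATES_8CELL, run_pair

DEFAULT_REPS = 300
DEFAULT_ALPHAS = (0.07, 0.08, 0.09, 0.10, 0.11, 0.12)
DEFAULT_WIDTHS: Mapping[str, Sequence[int]] = {
    "8-cell": CANDIDATES_8CELL,
    "7-cell": CANDIDATES_7CELL,
}

MODEL_NAMES = {1: "continuous", 8: "periodic", 16: "two-fold", 24: "three-fold",
               7: "periodic", 14: "two-fold", 21: "three-fold"}


def kl_distance(
    p: IntervalDistribution, q: IntervalDistribution, regularize: bool = True
) -> float:
    """D(p, q) = Σ p(x)·ln(p(x)/q(x)) over the union support (natural log).

    Terms with p(x) = 0 contribute nothing.  With ``regularize`` (the
    default), q receives the pseudo-count described in the module docstring;
    without it, q must already cover the support of p.
    """
    support = p.pmf.index.union(q.pmf.index)
    pv = p.pmf.reindex(support, fill_value=0.0).to_numpy()
    qv = q.pmf.reindex(support, fill_value=0.0).to_numpy()
    if regularize:
        eps = 1.0 / (q.n_obs + len(support))
        qc = qv * q.n_obs + eps
        qv = qc / qc.sum()
    mask = pv > 0
    if (qv[mask] <= 0).any():
        raise ValueError("q has zero mass on the support of p; enable regularization")
    return float(np.sum(pv[mask] * np.log(pv[mask] / qv[mask])))


@dataclass
class KLSample:
    """KL distances of one candidate model over repeated simulations."""

    z: int
    kl_values: np.ndarray

    def __post_init__(self) -> None:
        self.kl_values = np.asarray(self.kl_values, dtype=float)

    @property
    def mean(self) -> float:
        return float(self.kl_values.mean())

    @property
    def sd(self) -> float:
        return float(self.kl_values.std(ddof=1)) if len(self.kl_values) > 1 else 0.0

    @property
    def name(self) -> str:
        return MODEL_NAMES.get(self.z, f"z={self.z}")


@dataclass
class SelectionResult:
    samples: dict[int, KLSample]
    selected: int
    ks_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"z": z, "model": s.name, "mean_kl": s.mean, "sd_kl": s.sd,
                 "selected": z == self.selected}
                for z, s in sorted(self.samples.items())
            ]
        )


def simulate_interval_distribution(
    config: ModelConfig,
    seed_seq: np.random.SeedSequence,
    landmark: str = "pgc",
) -> IntervalDistribution | None:
    """Pooled (upper+lower) landmark-interval distribution of one paired run."""
    lattice, _ = run_pair(config, seed_seq=seed_seq)
    intervals = pooled_intervals(lattice, landmark=landmark)
    if intervals.size == 0:
        return None
    return IntervalDistribution.from_intervals(intervals, dt=config.dt)


def model_kl(
    experimental: IntervalDistribution,
    z: int,
    config: ModelConfig,
    reps: int = DEFAULT_REPS,
    seed: int | np.random.SeedSequence | None = None,
    landmark: str = "pgc",
) -> KLSample:
    """KL(experimental ‖ simulated) over ``reps`` fresh simulations at step z."""
    if reps < 1:
        raise ValueError(f"reps must be >= 1, got {reps}")
    cfg = config.with_(z=int(z))
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    values = []
    for child in ss.spawn(reps):
        q = simulate_interval_distribution(cfg, child, landmark=landmark)
        if q is None:  # landmark never advanced; vanishing-probability corner
            continue
        values.append(kl_distance(experimental, q))
    if not values:
        raise RuntimeError(f"no simulation at z={z} produced any landmark interval")
    return KLSample(z=int(z), kl_values=np.asarray(values))


def select(
    experimental: IntervalDistribution,
    candidates: Sequence[int] = CANDIDATES_8CELL,
    config: ModelConfig = ModelConfig(),
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
    landmark: str = "pgc",
) -> SelectionResult:
    """Rank candidate step sizes by mean KL distance; argmin wins.

    Also reports pairwise two-sample KS statistics between the candidates'
    KL-value samples.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate models")
    ss = np.random.SeedSequence(seed)
    samples = {
        int(z): model_kl(experimental, z, config, reps=reps, seed=child, landmark=landmark)
        for z, child in zip(candidates, ss.spawn(len(candidates)))
    }
    selected = min(samples, key=lambda z: samples[z].mean)
    rows = []
    zs = sorted(samples)
    for a_i, za in enumerate(zs):
        for zb in zs[a_i + 1:]:
            res = ks_2samp(samples[za].kl_values, samples[zb].kl_values)
            rows.append({"z_a": za, "z_b": zb,
                         "ks_stat": float(res.statistic), "p_value": float(res.pvalue)})
    return SelectionResult(samples=samples, selected=selected,
                           ks_table=pd.DataFrame(rows))


def sensitivity(
    experimental: IntervalDistribution,
    config: ModelConfig = ModelConfig(),
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    widths: Mapping[str, Sequence[int]] = DEFAULT_WIDTHS,
    reps: int = DEFAULT_REPS,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, float], SelectionResult]]:
    """Selection across a grid of transition probabilities and somite widths.

    Returns a tidy stability table (width, alpha_dt, selected z and model
    name, winner's mean KL) plus the full per-cell results.
    """
    ss = np.random.SeedSequence(seed)
    results: dict[tuple[str, float], SelectionResult] = {}
    rows = []
    cells = [(w, a) for w in widths for a in alphas]
    for (width, alpha), child in zip(cells, ss.spawn(len(cells))):
        res = select(
            experimental,
            candidates=widths[width],
            config=config.with_(alpha_dt=float(alpha)),
            reps=reps,
            seed=int(child.generate_state(1)[0] >> 1),
        )
        results[(width, alpha)] = res
        rows.append(
            {"width": width, "alpha_dt": alpha, "selected_z": res.selected,
             "selected_model": res.samples[res.selected].name,
             "mean_kl": res.samples[res.selected].mean}
        )
    return pd.DataFrame(rows), results


def window_oscillation_report(
    lattice: StateLattice, window: int = 8
) -> tuple[pd.DataFrame, float]:
    """Per-row window green-count series and their zero-lag synchrony.

    Returns the tidy series (frame, upper, lower; NA before a row has a PGC)
    and the zero-lag Pearson correlation of the two counts over frames where
    both rows have one (nan if fewer than two such frames or either series
    is constant).
    """
    records = []
    for t in range(lattice.t_max):
        rec = {"frame": t}
        for row in ROWS:
            rec[row] = window_green_count(lattice.row(row), t, window=window)
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    for row in ROWS:
        df[row] = df[row].astype("Int64")
    both = df["upper"].notna() & df["lower"].notna()
    u = df.loc[both, "upper"].to_numpy(float)
    l = df.loc[both, "lower"].to_numpy(float)
    if len(u) < 2 or np.ptp(u) == 0 or np.ptp(l) == 0:
        return df, float("nan")
    return df, float(pearsonr(u, l).statistic)
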