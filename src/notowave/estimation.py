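"""Estimation of the per-frame transition probability p = αΔt.

Once licensed, each cell's S-entry waiting time is geometric with success
probability p.  Because the wave reaches the upper and lower cell of a
position at the same time, the *signed difference* of paired entry frames is
the difference of two i.i.d. geometric variables, with the closed-form pmf

    g(t; p) = p·(1-p)^|t| / (2-p),   t ∈ ℤ,

symmetric in t and summing to one.  p is estimated by least-squares fitting
of g to the empirical difference pmf (derivative-free simplex search on the
logit scale, mirroring an fminsearch-style fit), which on real data gave
p ≈ 0.1101.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .containers import ROWS


def g_pdf(t, p: float):
    """Closed-form pmf of the difference of two independent geometric(p) trials.

    Accepts scalar or array ``t`` (signed integers).  For p = 1 both trials
    succeed at the first attempt and all mass sits at t = 0.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    t = np.asarray(t)
    out = p * (1.0 - p) ** np.abs(t) / (2.0 - p)
    return out if out.ndim else float(out)


def g_pdf_bruteforce(t: int, p: float, t_cap: int = 5000) -> float:
    """Truncated double-sum oracle: Σ_{t1-t2=t} f(t1)·f(t2) with
    f(s) = p(1-p)^(s-1).  Independent of the closed form; used to validate it.
    """
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    t2 = np.arange(1, t_cap + 1)
    t1 = t2 + t
    valid = t1 >= 1
    f = lambda s: p * (1.0 - p) ** (s - 1)
    return float((f(t1[valid]) * f(t2[valid])).sum())


@dataclass
class DifferenceSample:
    """Signed entry-frame differences t_upper − t_lower over paired cells."""

    diffs: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.diffs = np.asarray(self.diffs, dtype=int)

    def __len__(self) -> int:
        return len(self.diffs)


@dataclass
class FitResult:
    p_hat: float
    rss: float
    n_samples: int
    boundary: bool = False  # p_hat pinned near 1 (degenerate sample)


def collect_differences(table: pd.DataFrame) -> DifferenceSample:
    """Pair upper/lower entry frames by position; censored positions excluded."""
    wide = table.pivot(index="position", columns="row", values="entry_frame")
    for row in ROWS:
        if row not in wide.columns:
            raise ValueError(f"transition table lacks row {row!r}")
    both = wide["upper"].notna() & wide["lower"].notna()
    diffs = (wide.loc[both, "upper"] - wide.loc[both, "lower"]).to_numpy(int)
    return DifferenceSample(diffs=diffs, n_excluded=int((~both).sum()))


def empirical_pmf(diffs: np.ndarray) -> pd.Series:
    """Empirical pmf on every integer between min and max observed difference
    (zero-count bins included, so a fit is penalized for missing mass)."""
    diffs = np.asarray(diffs, dtype=int)
    if diffs.size == 0:
        raise ValueError("empty difference sample")
    support = np.arange(diffs.min(), diffs.max() + 1)
    counts = pd.Series(0, index=support, dtype=float)
    vc = pd.Series(diffs).value_counts()
    counts.loc[vc.index] = vc.to_numpy()
    return counts / counts.sum()


def fit_pmf(pmf: pd.Series, start: float = 0.2, folded: bool = False) -> FitResult:
    """Least-squares fit of g(·; p) to a pmf over its support.

    The simplex search runs on logit(p) so that p stays inside (0, 1)
    without explicit constraints.  With ``folded=True`` the pmf is folded to
    |t| and compared with g(t) + g(-t) (t > 0) and g(0).
    """
    support = pmf.index.to_numpy(int)
    target = pmf.to_numpy(float)
    n_samples = len(support)
    if folded:
        folded_pmf: dict[int, float] = {}
        for t, v in zip(support, target):
            folded_pmf[abs(int(t))] = folded_pmf.get(abs(int(t)), 0.0) + v
        support = np.array(sorted(folded_pmf))
        target = np.array([folded_pmf[t] for t in support])

    def model(p: float) -> np.ndarray:
        if folded:
            vals = g_pdf(support, p)
            return np.where(support == 0, vals, 2.0 * vals)
        return g_pdf(support, p)

    def objective(x: np.ndarray) -> float:
        return float(((model(expit(x[0])) - target) ** 2).sum())

    res = minimize(
        objective,
        x0=np.array([logit(start)]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 500},
    )
    p_hat = float(expit(res.x[0]))
    return FitResult(
        p_hat=p_hat,
        rss=float(res.fun),
        n_samples=n_samples,
        boundary=p_hat > 0.99,
    )


def fit_p(sample: DifferenceSample | np.ndarray, start: float = 0.2,
          folded: bool = False) -> FitResult:
    """Estimate p = αΔt from a sample of signed paired differences."""
    diffs = sample.diffs if isinstance(sample, DifferenceSample) else np.asarray(sample)
    if len(diffs) == 0:
        raise ValueError("cannot fit an empty difference sample")
    result = fit_pmf(empirical_pmf(diffs), start=start, folded=folded)
    result.n_samples = int(len(diffs))
    return result


def fit_p_mle(sample: DifferenceSample | np.ndarray) -> FitResult:
    """Maximum-likelihood cross-check (not the default estimator).

    Maximizes Σ log g(t_i; p); the least-squares fit on the empirical pmf is
    the primary route.
    """
    diffs = sample.diffs if isinstance(sample, DifferenceSample) else np.asarray(sample)
    if len(diffs) == 0:
        raise ValueError("cannot fit an empty difference sample")
    abs_sum = np.abs(diffs).sum()
    n = len(diffs)

    def nll(x: np.ndarray) -> float:
        p = float(expit(x[0]))
        return -(n * np.log(p) - n * np.log(2.0 - p) + abs_sum * np.log1p(-p + 1e-300))

    res = minimize(nll, x0=np.array([logit(0.2)]), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    p_hat = float(expit(res.x[0]))
    return FitResult(p_hat=p_hat, rss=float("nan"), n_samples=n, boundary=p_hat > 0.99)


def simulate_paired_differences(
    p: float, n_pairs: int, rng: np.random.Generator | int | None = None
) -> DifferenceSample:
    """Draw n_pairs independent geometric(p) pairs and return t₁ − t₂."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p must be in (0, 1], got {p}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    waits = rng.geometric(p, size=(n_pairs, 2))
    return DifferenceSample(diffs=waits[:, 0] - waits[:, 1])
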