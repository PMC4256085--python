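#!/usr/bin/env python
"""Linkage analysis: are upper and lower S-phase entries independent?

Compares observed cross-row green-pair counts in the 8-cell window with
Monte-Carlo expectations under a random null (independent rows) and a
biased null (q=0.9 coupling).  Two independent simulation rows — the model's
assumption — track the random null; a deliberately duplicated row tracks
the biased null instead, confirming the statistic can detect coupling.
"""

from pathlib import Path

import numpy as np

from notowave import ModelConfig, NullSpec, linkage_curves, run_pair
from notowave.containers import StateLattice
from notowave.io import write_table
from notowave.scoring import window_series

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)

cfg = ModelConfig(alpha_dt=0.1, z=16, n_cells=100, t_max=120, seed=404)
lattice, _ = run_pair(cfg)
spec = NullSpec(mode="random", q=0.9, reps=10_000, seed=11)

cases = {
    "independent": lattice,
    "duplicated": StateLattice.from_rows(
        lattice.row("upper"), lattice.row("upper").copy()
    ),
}
for tag, lat in cases.items():
    curves = linkage_curves(window_series(lat), spec)
    write_table(curves, RESULTS / f"linkage_curves_{tag}.tsv")
    ok = ~curves["skipped"].astype(bool)
    obs = curves.loc[ok, "observed"].to_numpy(float)
    rnd = curves.loc[ok, "random_null"].to_numpy(float)
    bias = curves.loc[ok, "biased_null"].to_numpy(float)
    mse_r = np.mean((obs - rnd) ** 2)
    mse_b = np.mean((obs - bias) ** 2)
    closer = "random" if mse_r < mse_b else "biased"
    print(
        f"{tag:<12} frames={ok.sum():3d}  MSE vs random={mse_r:5.2f}  "
        f"vs biased={mse_b:5.2f}  -> tracks the {closer} null"
    )

print(f"\nlinkage curve tables written to {RESULTS}/")
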