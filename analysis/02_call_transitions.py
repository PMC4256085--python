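#!/usr/bin/env python
"""Render synthetic Fucci traces and call G1/S transitions from them.

From a two-fold periodic simulation with known S-entry frames, renders
red-decay/green-rise intensity traces (with and without noise), applies the
crossing rule (green strictly above red for 5 consecutive frames) and
compares the called entry frames with the ground truth.  Noiseless traces
are recovered exactly; at the default noise level the caller stays within a
frame or two of the truth for almost every cell.
"""

from pathlib import Path

import numpy as np

from notowave import ModelConfig, TraceNoiseSpec, binarize, generate_lattice, render_traces
from notowave.io import write_traces, write_transitions

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"  # bulky trace tables
SCRATCH.mkdir(exist_ok=True)

cfg = ModelConfig(alpha_dt=0.1, z=16, n_cells=100, t_max=120, seed=2024)
_, truth = generate_lattice(cfg)
write_transitions(truth, RESULTS / "true_transitions.tsv")

for noise_sd, tag in [(0.0, "noiseless"), (50.0, "noisy")]:
    traces = render_traces(truth, TraceNoiseSpec(noise_sd=noise_sd), cfg, seed=7)
    write_traces(traces, SCRATCH / f"traces_{tag}.tsv")
    _, called = binarize(traces, persistence=5)
    write_transitions(called, RESULTS / f"called_transitions_{tag}.tsv")

    merged = truth.merge(called, on=["row", "position"], suffixes=("_true", "_called"))
    recoverable = merged["entry_frame_true"].notna() & (
        merged["entry_frame_true"] <= cfg.t_max - 5
    )
    sub = merged[recoverable]
    err = (sub["entry_frame_called"] - sub["entry_frame_true"]).astype(float).abs()
    print(
        f"{tag:<10} recoverable cells: {recoverable.sum():3d}  "
        f"exact: {(err == 0).mean():6.1%}  within 1 frame: {(err <= 1).mean():6.1%}  "
        f"max |error|: {np.nanmax(err.to_numpy()):.0f} frames"
    )

print(f"\ntransition tables written to {RESULTS}/; full traces to {SCRATCH}/")
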