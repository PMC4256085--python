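#!/usr/bin/env python
"""Simulate the wave model in its deterministic and stochastic regimes.

Runs the continuous (z=1), periodic (z=8) and two-fold periodic (z=16)
models at αΔt=1 (deterministic limit) and αΔt=0.1 (estimated probability),
writes the two-row lattices and per-frame G1/S totals under results/, and
reports the front geometry: at αΔt=1 the ARC sits directly behind the PGC
(zero-width transition window) and the periodic fronts advance every
30/60 min, while at αΔt=0.1 a mixed window opens between the landmarks.
"""

from pathlib import Path

import numpy as np

from notowave import ModelConfig, run_pair
from notowave.io import write_lattice, write_table
from notowave.scoring import arc_series, pgc_series, totals_series

RESULTS = Path(__file__).resolve().parents[1] / "results"
RESULTS.mkdir(exist_ok=True)
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"  # bulky tables
SCRATCH.mkdir(exist_ok=True)

for alpha, tag in [(1.0, "deterministic"), (0.1, "stochastic")]:
    for z, name in [(1, "continuous"), (8, "periodic"), (16, "two-fold")]:
        cfg = ModelConfig(alpha_dt=alpha, z=z, n_cells=100, t_max=120, seed=z)
        lattice, _ = run_pair(cfg)
        write_lattice(lattice, SCRATCH / f"lattice_{tag}_z{z}.tsv")
        write_table(totals_series(lattice), RESULTS / f"totals_{tag}_z{z}.tsv")

        up = lattice.row("upper")
        p, a = pgc_series(up), arc_series(up)
        both = ~np.isnan(p) & ~np.isnan(a)
        widths = a[both] - p[both] - 1  # cells strictly between ARC and PGC
        print(
            f"alpha_dt={alpha:<4} z={z:<3} ({name:<10}) "
            f"step={cfg.step_interval_minutes:5.2f} min  "
            f"mean window width={widths.mean():5.2f} cells "
            f"(max {int(widths.max())})"
        )

print(f"\ntotals tables written to {RESULTS}/; full lattices to {SCRATCH}/")
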