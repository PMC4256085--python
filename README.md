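# notowave

Quantitative analysis of the stochastic G1/S cell-cycle transition in the
developing zebrafish notochord.

In mid-sagittal section the embryonic notochord is two anterior→posterior
columns of cells whose nuclei, in a Fucci reporter line, switch from red (G1)
to green (S/G2/M) as development proceeds.  The switch is not synchronous: a
mixed red/green *transition window* travels posteriorly between the
all-green anterior cells and the newly formed red posterior cells.  This
package implements the full analysis chain used to ask what regulates that
window:

1. **Transition calling** — a cell's S-entry time is the first frame of a run
   of 5 consecutive frames with green intensity strictly above red.
2. **Scoring** — per frame and row, the posterior-most green cell (PGC), the
   anterior-most red cell (ARC), the green count in the 8-cell window ending
   at the PGC, and the cross-row green-pair count.
3. **Linkage analysis** — observed pair counts against Monte-Carlo random and
   biased (q = 0.9) null placements, testing whether upper and lower entries
   are independent.
4. **Wave model** — a Markov lattice model: a licensing wave with step size
   *z* cells advances at times *t_k = k·L_c·z/(λΔt)* (L_c = 5 µm cell
   diameter, λ = 4/3 µm/min elongation speed, Δt = 2.5 min frames), and every
   licensed G1 cell enters S independently with probability *αΔt* per frame.
   *z* = 1 is a continuous wave; *z* = 8 steps one somite width per 30-min
   segmentation-clock cycle; *z* = 16 and 24 are the two- and three-fold
   periodic modes (60 / 90 min).
5. **Probability estimation** — the signed difference of paired upper/lower
   entry times follows the difference-of-geometrics law
   *g(t; p) = p(1−p)^|t| / (2−p)*; least-squares fitting of *g* to the
   empirical difference distribution estimates *p = αΔt* (≈ 0.11 on real
   data; 0.1 is used as the working value).
6. **Model selection** — for each candidate *z*, the Kullback-Leibler
   distance *D(p, q) = Σ p(x)·ln(p(x)/q(x))* between the data's PGC
   waiting-time distribution *p* and the simulated distribution *q* is
   computed over 300 independent simulations; candidates are ranked by mean
   KL and compared pairwise with two-sample KS tests.

A synthetic-data module generates both noisy Fucci-like traces with known
crossing times and state lattices drawn from the wave model itself, so the
entire chain is testable without any imaging data.

## Worked example

Build a synthetic "experimental" PGC-interval distribution from three paired
two-fold simulations and run the selection (this is `analysis/06_select_model.py`):

```python
import numpy as np
from notowave import IntervalDistribution, ModelConfig, run_pair, select
from notowave.scoring import pooled_intervals

cfg = ModelConfig(alpha_dt=0.1, n_cells=100, t_max=240)
pooled = [pooled_intervals(run_pair(cfg.with_(z=16), seed_seq=c)[0])
          for c in np.random.SeedSequence(616).spawn(3)]
experimental = IntervalDistribution.from_intervals(np.concatenate(pooled))
result = select(experimental, candidates=(1, 8, 16, 24), config=cfg,
                reps=300, seed=617)
print(result.summary())
```

Output:

```
 z      model  mean_kl    sd_kl  selected
 1 continuous 1.866990 0.149293     False
 8   periodic 1.463042 0.129824     False
16   two-fold 1.021687 0.283090      True
24 three-fold 1.537413 0.313272     False
```

The two-fold periodic wave (z = 16, 60-min recurrence) attains the lowest
mean KL distance and is selected; every pairwise KS test on the KL samples
is significant at p < 0.001.  The numbered scripts under `analysis/` walk
through the full study — simulation regimes, trace calling, window scoring,
linkage nulls, probability estimation, selection and its sensitivity to
αΔt ∈ [0.07, 0.12] and to a 7-cell somite width — writing their tables under
`results/`.

A `notowave` command-line interface exposes the same stages
(`notowave synth lattice`, `call`, `score`, `linkage`, `simulate`,
`estimate`, `select`, `sensitivity`, `run-all`).

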