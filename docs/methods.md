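# Methods

## The stochastic lattice model

Notochordal cells are a 1-D lattice, index *i* = 1…n anterior→posterior,
observed on a 2.5-min frame grid.  A licensing wave with step size *z* cells
fires at times *t_k = k·L_c·z/(λΔt)* (frame units, k ≥ 1), so the front
position at frame *t* is *z·#{k : t_k ≤ t}* and cell *i* is licensed when
the signal-transmitting condition *f(i,t) = i − z·#{k : t_k ≤ t} ≤ 0* holds.
Every licensed G1 cell enters S independently with probability *αΔt* per
frame; there is no reverse transition, no division, movement or 2-D
geometry.  With the measured constants (L_c = 5 µm, λ = 4/3 µm/min,
Δt = 2.5 min, 30-min segmentation clock) one somite width is
T·λ/L_c = 8 cells, and z ∈ {8, 16, 24} gives wave recurrence 30/60/90 min;
z = 1 is the continuous limit (front advances one cell per 1.5 frames).

Parameters (`ModelConfig`): `alpha_dt` (default 0.1, the working value near
the fitted 0.1101), `z` (default 16), `L_c` = 5 µm, `lam` = 4/3 µm/min,
`dt` = 2.5 min, `T_som` = 30 min, `n_cells` = 100, `t_max` = 120 frames
(300 min, the span of a live-imaging session); selection experiments use
`t_max` = 240 so several two-fold wave steps fall inside the record.

**Step-index convention.**  The wave count starts at k = 1, so no cell is
licensed before *t_1*; the alternative with cells 1…z licensed from frame 0
is exposed as `license_from_k0` but is not the default.  All cells are G1 at
frame 0; a cell licensed at frame ℓ can first appear in S at frame
max(ℓ, 1).

**Sampling.**  `simulator.run` draws each cell's post-licensing waiting time
directly from the geometric distribution instead of looping per-frame
Bernoulli trials — identical in distribution because cells are independent,
and orders of magnitude cheaper for the repeated simulations of the
selection stage.  A unit test verifies the per-frame transition fraction of
licensed G1 cells against *αΔt* binomially.  Paired (upper/lower) runs share
the wave schedule but use independent child streams of one seed sequence.
Non-integer *t_k* (e.g. 1.5 k frames at z = 1) are compared against the
integer frame grid with a 1e-9 guard.

## Transition calling

S entry is called at the earliest frame *t* such that green > red strictly
at all frames *t … t+4* (persistence 5).  Ties break the run; a run
truncated by the end of the trace does not count, so entries within the
last 4 frames of a record are censored.  Channels are compared as recorded
(no smoothing or normalization; upstream averaging of the nuclear area is
out of scope here).  The called time is the first frame of the run — the
crossing frame.

## Synthetic data

`synth.generate_lattice` is the model itself (two independent rows plus the
true entry table).  `synth.render_traces` emulates the Fucci color switch
with logistic red-fall/green-rise curves: peaks 1000 AU, 10–90% transition
over `rise_width` = 8 frames, additive Gaussian noise (`noise_sd` = 50 AU by
default, chosen so the caller's error is nontrivial but small — ~3% of calls
off by one frame, none further).  The continuous crossing is placed half a
frame *before* the true entry frame: on the frame grid the entry frame is
then the first sample where green strictly exceeds red, which makes the
noiseless round trip (truth → traces → caller) exact under the
strict-inequality calling rule; centering the crossing exactly on the entry
frame would produce a tie there and shift every call by one frame.  Censored
cells get a flat red-dominant pair.  What the generator does **not**
emulate: intensity drift/bleaching, cell movement or tracking errors,
segmentation noise, division — so green tests certify the statistical chain,
not image processing.

## Scoring

PGC = largest S index in a row, ARC = smallest G1 index.  The transition
window is the PGC plus the 7 cells anterior to it; when the PGC is within
the first 8 positions the window is clipped at the boundary and flagged.
Pair counts use the lower-row PGC as landmark (configurable).  PGC/ARC
waiting times are recorded per advance *event* — a jump of several cells is
one event — and the first appearance starts the clock without contributing
an interval.  Intervals are kept in frames internally; minutes (×2.5) only
at reporting.  In the deterministic limit (αΔt = 1) the window has zero
width: ARC = PGC + 1 at every frame, the discrete expression of the two
landmarks coinciding (and the window green count is constantly 8, so the
cross-row synchrony correlation is undefined there; the stochastic regime is
where it is informative).

## Linkage nulls

Per frame, given the observed green counts (g_u, g_l) in the 8-cell window:
the random null places both rows' greens uniformly on distinct sites
(expected overlap g_u·g_l/8, verified against exhaustive enumeration); the
biased null places the upper row at random, then repeatedly picks a
uniformly random still-red lower site which turns green with probability
q = 0.9 if its upper partner is green (1−q otherwise) until g_l greens are
placed.  Expectations are Monte-Carlo means over 10,000 placements.  The
sequential biased process admits an exact recursion (conditioning on the
next successful placement), used as the test oracle.  No formal hypothesis
test is attached; the statistic is a goodness-of-tracking comparison.

## Probability estimation

For paired cells the licensing time cancels, so the signed entry-time
difference follows g(t; p) = p(1−p)^|t|/(2−p) — derived by summing the joint
geometric pmf along diagonals and validated in-code against a truncated
double sum (< 1e-10 over |t| ≤ 50).  The empirical difference pmf is built
on every integer between the observed min and max (zero bins included) and
g is fitted by Nelder-Mead simplex on logit(p) (start p = 0.2), minimizing
the residual sum of squares.  Folded (|t|) fitting and a maximum-likelihood
estimator are provided as cross-checks only.  A sample of all-zero
differences drives p̂ to the boundary and is flagged.

## Model selection

KL distance D(p, q) = Σ p·ln(p/q) in nats over the union support, data
distribution as p, simulation as q.  Because q is an empirical pmf from one
simulation replicate, it is regularized with a pseudo-count
ε = 1/(N_q + S) per union-support point (N_q simulated intervals, S support
size) before normalization — this keeps D finite and ≥ 0 while leaving
well-populated bins essentially untouched; p is never regularized (its zero
terms contribute nothing).  Each candidate's KL is computed over 300
independent paired simulations (pooling upper+lower intervals per
replicate), candidates ranked by mean, and KL samples compared pairwise
with two-sample KS tests (asymptotic p-values).  The sensitivity sweep
repeats selection over αΔt ∈ {0.07…0.12} and the 7-cell-somite candidate
set {1, 7, 14, 21} (z = 7 period 26.25 min).

**Problem sizes.**  The recovery experiments use a synthetic experimental
distribution pooled from three paired z = 16 runs (n = 100, t_max = 240),
mirroring the three-specimen pooling of real recordings, and 50 KL repeats
per candidate in the 20-seed recovery loop (300 repeats wherever a single
selection is reported).  These sizes give a 19/20 recovery rate of the
two-fold truth and stable KS separation while keeping every driver and the
test suite fast.

## Known limitations

- The model has one free parameter by design; it cannot express
  cell-autonomous timing gradients or coupling between neighbors (the
  linkage analysis is what justifies ignoring the latter).
- Interval distributions are frame-resolved (2.5-min bins); sub-frame
  timing is not modeled.
- ARC-based intervals carry little wave information (confirmed by a
  directional test: ARC self-selection never beats PGC self-selection), so
  all selection defaults use the PGC.
- The pseudo-count rule for q is one reasonable choice among several; all
  reported KL comparisons are made under this exact rule, and conclusions
  should be read as conditional on it.
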