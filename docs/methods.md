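# Methods

This note records the models implemented in oscillome, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic data can and cannot show.

## Structural connectome

A whole-brain SC is assembled from single-hemisphere ipsilateral and
contralateral projection blocks under bilateral symmetry: the 2h-node
matrix is `[[ipsi, contra], [contra, ipsi]]`, hemisphere A first. We adopt
the convention that hemisphere A occupies indices 0..h−1 and is the "first
hemisphere" targeted by unilateral injury; nothing downstream depends on
which hemisphere is literally left or right. Weights follow row = source,
column = target throughout.

Normalization zeroes self-connections first and then rescales by the
off-diagonal maximum, so the strongest edge has weight exactly 1. Zeroing
first only matters in the degenerate case where the global maximum is a
self-connection; normalization is idempotent. Reducing an SC to a region
subset (to match a subject's surviving FC regions) deliberately does *not*
re-normalize, so reduced and full networks share one edge scale.

The randomized null model is a seeded, directed, degree-preserving edge
swap (pairs of edges `(b1→a1),(b2→a2)` rewired to `(b1→a2),(b2→a1)` when
no self-loop or duplicate results), each edge swapped 20 times on average.
Weights travel with their source stub, so in-/out-degree sequences and the
global weight multiset are conserved exactly, while in-/out-strength
sequences are preserved only distributionally (verified by two-sample K-S
in the tests). The undirected null is the direction sum of the randomized
directed network.

Weighted global efficiency is the mean over ordered node pairs of the
inverse shortest-path length, with edge length = 1/weight and unreachable
pairs contributing zero (the standard convention for possibly disconnected
graphs). Shortest paths use Dijkstra via `scipy.sparse.csgraph`.

## Kuramoto dynamics

Phases obey dθ_a/dt = ω_a + g Σ_b A_ba sin(θ_b − θ_a) — the synchronizing
sign convention, which is the one consistent with every behavior the model
is meant to show (synchronization with rising g, a metastability peak).
Natural frequencies are uniform on [0.01, 0.1] Hz × 2π; initial phases
uniform on [0, 2π). No time delays, noise, or hemodynamic convolution: at
BOLD-band frequencies and mouse-brain distances, delays are negligible
relative to oscillation periods.

Integration is fixed-step RK4 with dt = 0.05 s and output sampling every
0.5 s; the fastest natural period is 10 s, so the step is heavily
oversampled, and halving dt changes synchrony and metastability by less
than 10⁻³ on test networks (asserted). A guard warns when
dt·max|dθ/dt| > 0.5 rad (reachable only at extreme couplings). Baseline
protocol: 600-s runs discarding the first 120 s; optimization iterations
use 200-s runs discarding the first 20% (40 s) — the transient fraction is
kept fixed rather than the absolute duration so shorter runs scale
consistently.

Simulated FC is the pairwise Pearson correlation of sin θ over the
post-transient samples. A constant sin-trace (possible only in fully
locked corner cases) has undefined correlations; its edges are set to 0
with a warning.

## Empirical-FC quality control

Three sequential filters per recording: (1) keep regions whose labels
match the SC; (2) keep regions with voxel count strictly above the median
of the post-(1) cohort — ties at the median are excluded; (3) drop regions
with time-series variance below 10⁻⁶. Network comparisons (including the
simulated-vs-target *predictive power*) are Pearson correlations over
strictly-upper-triangle edges of the common-region submatrices, using raw
signed correlations with no thresholding.

## Frequency optimization

The update loop alternates simulation and a control-energy-weighted
frequency step. Several ingredients of the published recipe are not fully
specified anywhere; the choices below are exposed in the API and fixed as
defaults:

- **Stabilization.** A_stab = W/(1 + λ_max) − I with λ_max the largest
  eigenvalue magnitude of W. This is the common network-control
  convention; it guarantees all eigenvalue real parts are negative.
- **Horizon and quadrature.** T = 1 (dimensionless), controllability
  Gramian and energy integrals by Simpson's rule on a 201-point uniform
  grid, with matrix exponentials built by repeated multiplication of
  `expm(A·dt)`. The per-node energies satisfy the decomposition identity
  Σ_a E_a = (x_T − e^{AT}x_0)' W_T⁻¹ (x_T − e^{AT}x_0) to ~10⁻¹⁰ relative,
  and match a discretized least-norm brute-force control within 1% on
  small systems (asserted). A near-singular Gramian (condition > 10¹²) is
  regularized with documented jitter and a warning.
- **Energy normalization.** E is normalized to unit maximum each
  iteration, so the step constant c = 0.005 controls step size regardless
  of network scale; the step is c · (0.09 Hz × 2π) · Ê_a · (s_sim − s_emp).
- **Update sign.** The strength difference is taken literally as
  (s_sim − s_emp); a sign flag is exposed for the opposite reading.
- **Shared initial frequencies.** Initial ω is keyed by region label
  (hashed into a per-label seeded draw), so a region receives the same
  starting frequency in every subject's model regardless of which other
  regions survived that subject's quality control.
- **Determinism.** Initial phases are drawn once per optimization and
  reused across iterations, so successive iterations differ only through
  the frequencies. Updated frequencies are floored at 2π×10⁻⁴ rad/s and
  may exceed the 0.1 Hz band; the run aborts if any frequency exceeds ten
  times the band maximum.

Fits run at the coupling of approximate maximum metastability for the
network at hand (the regime where dynamics are most flexible); for the
default synthetic generator this lands near g ≈ 2 on the directed
architecture.

## Injury model

A lesion scales all edges into and out of the targeted hemisphere-A nodes
by (1 − f). The scaling is one mask multiplication, so an edge between two
targeted nodes is scaled exactly once per application — composing
fractions f then g therefore equals a single application of
1 − (1−f)(1−g) on every touched edge (asserted). Severity runs from 5% to
100% in 5% steps (20 injured networks per model). Target regions default
to the 14 cortical/hippocampal areas that degenerate after mild controlled
cortical impact, shipped as a packaged table with exclusion flags; regions
absent from a reduced model are skipped silently and counted.

Injured simulations reuse the optimized frequencies, the same initial
phases, and the same seed as the uninjured baseline, so FC changes are
attributable to structure alone. The functional readout per level is the
edge-strength correlation to baseline, the mean regional FC distance to
baseline (per-node Euclidean row distance over shared, non-injured
columns; a whole-matrix Frobenius variant is also provided), and
structural global efficiency. The hypo-/hyperconnectivity analysis
restricts to regions common to all models and not directly injured,
computes nodal strengths on that common submatrix, and reports the
fraction of models whose strength strictly decreased (ties count as
not-decreased) per region and level.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- **Connectome.** Log-normal weights (heavy-tailed, like tract-tracing
  strengths) at a requested directed-edge density, with a direction-bias
  parameter giving each connected pair a single dominant direction with
  probability 0.7 by default; blocks are mirrored bilaterally and
  normalized. The weight scale parameter defaults to σ = 2: this places
  the default network in the partially synchronized, metastable regime at
  moderate coupling (synchrony well below 1 at the metastability peak,
  undirected variants synchronizing at lower g than directed), which is
  the regime the whole analysis lives in. Lighter tails (σ ≈ 1) make the
  normalized network so homogeneous that it locks fully at any useful g
  and FC degenerates to all-ones.
- **Targets.** `self_consistent` targets are simulated FC from known
  frequencies on the dropout-reduced network — the optimizer's
  ground-truth recovery case. `noisy` targets are factor-model correlation
  matrices steered to a requested edge-strength mean and SD (defaults
  0.2/0.15, in the range typical of anesthetized-mouse FC) and projected
  to the nearest correlation matrix (statsmodels). Dropout sizes default
  to 115–146 surviving regions out of 178 candidates, matching the
  QC-driven network sizes of the empirical regime; desk-scale runs scale
  this fraction down.
- **BOLD.** Gaussian series with the target correlation (Cholesky of the
  clipped-PD matrix), a constructed number of near-constant regions
  (variance < 10⁻⁶) that must fall to the variance filter, and distinct
  voxel counts arranged so exactly half the regions pass the median
  filter, with violators always among the passers.

What passing tests on these data show: the pipeline's bookkeeping,
conservation laws, analytic limits, and the *direction* of every headline
trend (architecture and randomization effects, optimization gains, injury
dose responses). What they cannot show: empirical effect sizes. Synthetic
targets lack anesthesia structure, spatial embedding, and measurement
noise; desk-scale networks are ~60 nodes rather than 426. In particular,
the hypo/hyper balance at severe injury is sensitive to network size and
density, and small dense synthetic models can show proportionally more
hyperconnectivity at extreme lesion levels than large sparse ones.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
60-node connectomes, 5-seed sweeps at a 0.2 coupling step, 150-s baseline
runs, 25-iteration optimizations with 60-s iterations, and three injured
models. The full-scale protocol (426 nodes, 0.1 steps, 25 seeds, 600-s
runs, 100 iterations, 58 subjects) is what the defaults of the library and
CLI encode; it is reachable by changing configuration only.
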