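# oscillome

Kuramoto whole-brain network models on directed connectomes: simulated
functional connectivity, control-energy-guided frequency optimization, and
graded connectivity-injury sweeps.

## The problem

Mesoscale tract tracing gives a *directed*, weighted structural connectome
(SC) of the mouse brain, while resting-state BOLD fMRI gives per-subject
functional connectivity (FC) — the matrix of pairwise Pearson correlations
between regional activity. This package connects the two with a
deliberately simple dynamical model, then asks how simulated FC degrades
when the structural network is progressively injured, as in experimental
models of traumatic brain injury (TBI).

Each brain region *a* is a phase oscillator with a natural frequency
ω_a drawn from the BOLD band ([0.01, 0.1] Hz × 2π):

    dθ_a/dt = ω_a + g · Σ_b A_ba · sin(θ_b − θ_a)

where A_ba is the structural weight directed from region *b* to region *a*
and *g* a global coupling gain. Synchrony and metastability are the time
mean and SD of the order parameter R(t) = |⟨e^{iθ}⟩|; simulated FC is the
pairwise correlation of sin θ, and *predictive power* is the Pearson
correlation between simulated and target FC edge strengths.

To fit a model to one subject's FC, natural frequencies are updated
iteratively. After each simulation, node *a*'s frequency moves by

    Δω_a = c · (ω_hi − ω_lo) · Ê_a · (s_sim,a − s_emp,a),   c = 0.005

where s are nodal FC strengths (sums of positive incident edges) and Ê_a
is the node's minimum control energy — E_a = ∫₀ᵀ u*_a(t)² dt for the
minimum-energy input u* driving a stabilized linear surrogate
dx/dt = Ax + Bu from the simulated to the target strength profile —
normalized to unit maximum. Nodes that are expensive to steer get larger
frequency corrections.

Injury is modeled by scaling all edges into and out of a set of lesioned
regions (by default 14 cortical/hippocampal areas that degenerate after
mild controlled cortical impact) in one hemisphere by 1 − f, for
f = 0.05 … 1.00 in 5% steps, then re-simulating FC with the optimized
frequencies and measuring structural global efficiency, FC correlation and
mean regional FC distance to the uninjured baseline, and per-region
frequencies of FC strength decrease (hypo- vs hyperconnectivity).

All external data dependencies are replaced by a first-class synthetic
module: bilaterally mirrored log-normal connectomes with directional bias,
factor-model or self-consistent target FC with region dropout, and
Gaussian BOLD-like series with built-in quality-control casualties.

## Worked example

```python
import oscillome as om

cfg = om.SynthConfig(regions_per_hemisphere=30, dropout_range=(40, 52), seed=1)
sc = om.synth_connectome(cfg)                      # 60-node directed SC

# where is this network most metastable?
sweep = om.coupling_sweep(sc, [0.5, 1.0, 1.5, 2.0, 2.5], n_seeds=3, seed=0,
                          duration_s=200, transient_s=40)
print(sweep[["g", "synchrony", "metastability"]].round(3))
#      g  synchrony  metastability
# 0  0.5      0.163          0.079
# 1  1.0      0.246          0.133
# 2  1.5      0.337          0.148
# 3  2.0      0.488          0.161
# 4  2.5      0.558          0.150

# fit frequencies to a target FC generated from known ground-truth ω
target, omega_true = om.synth_target_fc(sc, "self_consistent", cfg,
                                        seed=100, g=2.0, duration_s=200)
sub = om.reduce_to_regions(sc, target.regions)
trace = om.optimize(sub, target, g=2.0, n_iter=25, iter_duration_s=60, seed=0)
print(round(trace.pp_history[0], 3), round(trace.best_pp, 3))
# 0.197 0.265        # predictive power before vs after optimization

# injure the optimized model at 20 severities
spec = om.InjurySpec(target_regions=tuple(r[:-2] for r in sub.regions[:5]))
result = om.injury_sweep(sub, trace.best_omega, g=2.0, spec=spec, seed=0,
                         duration_s=60)
print(result.table.head(3).round(4))
#    level  corr_to_baseline  mean_distance  global_efficiency
# 0   0.05            0.9033         1.0405             0.0167
# 1   0.10            0.8666         1.2323             0.0165
# 2   0.15            0.8215         1.4217             0.0163
```

The sweep shows the usual picture: synchrony rises monotonically with the
coupling gain while metastability peaks at an intermediate g (here ≈ 2),
the regime where network dynamics are most flexible. Optimization raises
the match to the target FC (0.20 → 0.27 here in 25 short iterations), and
the injury table shows the dose response: correlation to the uninjured FC
falls and structural global efficiency decreases as connectivity loss
grows.

The same stages are available from a shell:

```bash
oscillome build-sc --synthetic --regions-per-hemisphere 30 --seed 1 --out-dir run/
oscillome sweep-g --sc run/sc_directed.csv --arch directed --out run/sweep.csv
oscillome fit --sc run/sc_directed.csv --target run/target_fc.csv --out-dir run/
oscillome injure --sc run/sc_directed.csv --omega run/fit_omega.npz --g 2.0 \
    --out run/injury.csv
oscillome report --injury-tables run/injury.csv --out-dir run/
```

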