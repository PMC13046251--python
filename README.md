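# chimerapred

Chimera-state detection and physics-informed seizure prediction on
coupled-oscillator models of multichannel EEG.

Chimera states — network regimes in which one group of coupled
oscillators phase-synchronizes while another stays incoherent — have
been reported as EEG biomarkers appearing tens of minutes before
epileptic seizures. This package provides the full computational stack
for studying that idea on simulated data with known ground truth:

* a **Kuramoto–Sakaguchi generator** producing labeled synthetic EEG
  episodes with a realistic pre-seizure progression (baseline →
  chimera emergence → stabilization → transition → ictal global
  synchrony → post-ictal recovery);
* the **detection pipeline**: resampling / zero-phase Butterworth
  bandpass / ICA artifact criteria / interictal z-scoring, Hilbert
  instantaneous phases, windowed Phase Locking Values (PLV), adaptive
  adjacency refinement, 3-clique hypergraph construction, spectral
  communities and per-cluster Kuramoto order parameters;
* a **physics-informed neural network** (hypergraph convolutions +
  selective state-space temporal blocks + multi-task heads) trained
  with Kuramoto-consistency and chimera-structure losses, implemented
  on a small NumPy reverse-mode autodiff engine authored in-package;
* an **evaluation harness**: stratified episode-level cross-validation,
  alarm aggregation, horizon sensitivity, false positives per hour,
  bootstrap confidence intervals and Cohen's kappa.

## The model

Oscillator phases follow the Kuramoto–Sakaguchi dynamics

    dθᵢ/dt = ωᵢ + (1/C) Σⱼ K_ij sin(θⱼ − θᵢ − α)

with `K_ij = K` inside a community and `r·K` across communities
(two-population topology; defaults `K = 0.71`, `α = 0.28 rad`,
`r = 0.7`, 23 channels split 12/11). The synchronized community
oscillates in the pathological delta band (2.3 Hz), the desynchronized
community in the alpha band (9.1 Hz ± 1.3 Hz).

A 5-second analysis window is **chimera-labeled** when the
order-parameter contrast between spectral communities of the PLV matrix
exceeds 0.3:

    R_k = |Σ_{j∈k} exp(iφⱼ)| / N_k ,   max(R_k) − min(R_k) > 0.3

Electrode triplets whose pairwise connectivities all exceed τ = 0.65
form hyperedges; the network aggregates over these with learned
attention, models the window sequence with input-selective linear
state-space recurrences, and its physics heads read out interpretable
(θ̂, ω̂, K̂, α̂) that a Kuramoto-consistency loss keeps on the
oscillator-dynamics manifold.

## Worked example

```python
import numpy as np
from chimerapred import (KuramotoParams, simulate_kuramoto,
                         estimate_kuramoto_params, EpisodeSpec,
                         generate_episode, analytic_phase, plv_matrix,
                         spectral_clusters, order_parameter,
                         detect_3cliques, hyperedge_density, refine_adjacency)

# 1. simulate the default two-community network in the chimera regime
params = KuramotoParams.chimera_default(seed=1)
traj = simulate_kuramoto(params, duration=60.0, dt=1/256, seed=1)
tail = traj.phases[-2560:]
for c in (0, 1):
    members = params.community == c
    R = np.abs(np.exp(1j * tail[:, members]).mean(axis=1)).mean()
    print(f"community {c}: <R> = {R:.3f}")

# 2. invert the dynamics by least squares (mean-field topology, r = 1,
#    where the regression is correctly specified)
mf = KuramotoParams.chimera_default(seed=1, inter_coupling_ratio=1.0)
fit = estimate_kuramoto_params(simulate_kuramoto(mf, 60.0, 1/256, seed=1))
print(f"recovered K = {fit.coupling_K:.3f} (true 0.71), "
      f"alpha = {fit.phase_lag_alpha:.3f} rad (true 0.28)")

# 3. run the detection pipeline on a full labeled episode
episode = generate_episode(EpisodeSpec(seed=1))
phases = analytic_phase(episode.signal)
plvs = plv_matrix(phases)
mid = plvs[len(plvs) // 2]           # a stabilization-segment window
assign = spectral_clusters(mid, k=2, seed=0)
i0, i1 = int(mid.window[0] * 256), int(mid.window[1] * 256)
R = [np.mean([order_parameter(row[assign.members(c)])
              for row in phases.phases[i0:i1:16]]) for c in (0, 1)]
print(f"window {mid.window}: cluster R = {R[0]:.2f} / {R[1]:.2f}, "
      f"contrast = {abs(R[0]-R[1]):.2f}")

hg = detect_3cliques(refine_adjacency(None, mid), tau=0.65)
print(f"hyperedges: {hg.n_hyperedges} "
      f"(density {100*hyperedge_density(hg):.1f}% of C(23,3))")
```

prints

```
community 0: <R> = 0.995
community 1: <R> = 0.305
recovered K = 0.707 (true 0.71), alpha = 0.280 rad (true 0.28)
window (448.0, 453.0): cluster R = 0.21 / 0.99, contrast = 0.78
hyperedges: 221 (density 12.5% of C(23,3))
```

The first two lines are the chimera signature (one community locked,
one incoherent); the recovery line shows the vector-field regression
returning the programmed coupling and phase lag; the last two lines
show a stabilization-segment window far above the 0.3 chimera-contrast
threshold and a hyperedge density inside the 10–30 % operating range.

Training the network on a synthetic benchmark:

```python
from chimerapred import ChimeraNetwork
from chimerapred.episodes import EpisodeSpec, generate_episode

episodes = [generate_episode(EpisodeSpec.desk(seed=100 + i)) for i in range(40)]
net = ChimeraNetwork(max_epochs=30, random_state=0)
net.fit(episodes[:34], val_episodes=episodes[34:])
print(net.best_val_accuracy_)        # window-level chimera accuracy ~0.9
```

A command-line interface mirrors the library:
`chimerapred simulate | preprocess | detect-chimera | build-hypergraph |
train | evaluate` (see `chimerapred --help`).

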