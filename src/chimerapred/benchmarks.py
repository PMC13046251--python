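"""Calibration benchmarks: parameter recovery, band-frequency recovery,
chimera-contrast and hypergraph-density measurements, and the desk-scale
learnability experiment.

These functions define the package's reference experiments at their
standard problem sizes (20 recovery seeds, 10 fixture seeds, 20 default
episodes, 40 training episodes); both the test suite and the acceptance
script run them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .chimera import chimera_label, order_parameter, spectral_clusters
from .core import PhaseTrajectory
from .episodes import EpisodeSpec, generate_episode, phases_to_signal
from .hypergraph import detect_3cliques, hyperedge_density, refine_adjacency
from .kuramoto import (DEFAULT_COUPLING_K, DEFAULT_PHASE_LAG, KuramotoParams,
                       estimate_kuramoto_params, simulate_kuramoto)
from .losses import LossWeights
from .model import HPGNNCore, ModelConfig, StateSpaceConfig
from .phase import analytic_phase, plv_matrix
from .training import TrainConfig, chimera_accuracy, featurize_episode, train

__all__ = [
    "coupling_recovery",
    "band_frequency_recovery",
    "stabilization_contrast",
    "hyperedge_density_percent",
    "learnability_experiment",
]

RATE = 256.0


def coupling_recovery(seeds=tuple(range(1, 21)), duration: float = 60.0,
                      phase_noise_sd: float = 0.05) -> dict[str, float]:
    """Mean recovered (K, alpha) over seeded simulations of the default
    23-oscillator network at the chimera operating point.

    The recovery simulations use mean-field topology (inter-community
    ratio 1) because the least-squares estimator regresses on the
    mean-field vector field; under the two-community default (r = 0.7)
    the pooled estimate is deliberately misspecified and biased low.
    Observation noise of ``phase_noise_sd`` radians is added to the
    phases before fitting.
    """
    ks, alphas = [], []
    for seed in seeds:
        params = KuramotoParams.chimera_default(seed=seed,
                                                inter_coupling_ratio=1.0)
        traj = simulate_kuramoto(params, duration, 1.0 / RATE, seed=seed)
        rng = np.random.default_rng(10_000 + seed)
        noisy = PhaseTrajectory(
            traj.phases + rng.normal(0.0, phase_noise_sd, traj.phases.shape),
            dt=traj.dt)
        fit = estimate_kuramoto_params(noisy)
        ks.append(fit.coupling_K)
        alphas.append(fit.phase_lag_alpha)
    return {
        "coupling_K": float(np.mean(ks)),
        "phase_lag_alpha": float(np.mean(alphas)),
        "true_K": DEFAULT_COUPLING_K,
        "true_alpha": DEFAULT_PHASE_LAG,
        "n": len(list(seeds)),
    }


def band_frequency_recovery(seeds=tuple(range(1, 11)), duration: float = 120.0,
                            noise_sd: float = 0.1) -> dict[str, float]:
    """Mean Hilbert-phase instantaneous frequency (Hz) per community on
    the stabilization fixture.

    Per channel the estimate is the mean phase derivative over the
    guarded interior divided by 2 pi, averaged over community members
    and seeds.
    """
    sync_means, desync_means = [], []
    for seed in seeds:
        params = KuramotoParams.chimera_default(seed=seed)
        traj = simulate_kuramoto(params, duration, 1.0 / RATE, seed=seed)
        sig = phases_to_signal(traj, 1.0, noise_sd, seed=20_000 + seed)
        rec = analytic_phase(sig)
        interior = rec.interior_slice()
        unwrapped = np.unwrap(rec.phases[interior], axis=0)
        freqs = (unwrapped[-1] - unwrapped[0]) / (
            (unwrapped.shape[0] - 1) * rec.dt) / (2 * np.pi)
        sync_means.append(freqs[params.community == 0].mean())
        desync_means.append(freqs[params.community == 1].mean())
    return {
        "f_sync_hz": float(np.mean(sync_means)),
        "f_desync_hz": float(np.mean(desync_means)),
        "n": len(list(seeds)),
    }


def stabilization_contrast(seeds=tuple(range(1, 21)),
                           episodes=None) -> dict[str, float]:
    """Median order-parameter contrast between the two spectral
    communities across stabilization-segment windows of default episodes.

    Runs the full pipeline — signal, Hilbert phases, 5-s/50 % PLV,
    spectral clustering with k = 2, per-cluster order parameters — and
    pools the per-window contrast over windows and seeds.
    """
    if episodes is None:
        episodes = [generate_episode(EpisodeSpec(seed=s)) for s in seeds]
    contrasts = []
    for ep in episodes:
        traj = analytic_phase(ep.signal)
        a, b = ep.segment_boundaries["stabilization"]
        for m in plv_matrix(traj):
            if not (m.window[0] >= a and m.window[1] <= b):
                continue
            assign = spectral_clusters(m, k=2, seed=0)
            i0 = int(round(m.window[0] * RATE))
            i1 = int(round(m.window[1] * RATE))
            theta = traj.phases[i0:i1]
            rs = np.array([
                np.mean([order_parameter(row[assign.members(c)])
                         for row in theta[:: 16]])
                for c in range(2)
            ])
            contrasts.append(chimera_label(rs)[0])
    return {"median_contrast": float(np.median(contrasts)),
            "n": len(contrasts)}


def hyperedge_density_percent(seeds=tuple(range(1, 11)),
                              duration: float = 120.0,
                              noise_sd: float = 0.1,
                              tau: float = 0.65,
                              windows_per_seed: int = 8) -> dict[str, float]:
    """Mean 3-clique density (percent of C-choose-3) at the clique
    threshold on identity-refined PLV matrices of the stabilization
    fixture."""
    densities = []
    for seed in seeds:
        params = KuramotoParams.chimera_default(seed=seed)
        traj = simulate_kuramoto(params, duration, 1.0 / RATE, seed=seed)
        sig = phases_to_signal(traj, 1.0, noise_sd, seed=30_000 + seed)
        rec = analytic_phase(sig)
        for m in plv_matrix(rec)[:windows_per_seed]:
            adj = refine_adjacency(None, m)
            densities.append(hyperedge_density(detect_3cliques(adj, tau)))
    return {"density_percent": float(100.0 * np.mean(densities)),
            "n": len(densities)}


def learnability_experiment(
    episode_seeds=tuple(range(100, 140)),
    model_seeds=(0, 1, 2),
    variants=("full",),
    max_epochs: int = 30,
    episodes=None,
) -> dict[str, dict]:
    """Desk-scale training benchmark: 40 compact episodes, reduced model,
    30 epochs; reports per-variant held-out window-level chimera accuracy.

    Variants: ``full`` (hypergraph + physics losses), ``no-physics``
    (physics and structure weights zeroed), ``pairwise`` (2-node edges
    instead of triplet hyperedges, physics losses zeroed).
    """
    if episodes is None:
        episodes = [generate_episode(EpisodeSpec.desk(seed=s))
                    for s in episode_seeds]
    cache: dict[bool, list] = {}

    def data_for(pairwise: bool):
        if pairwise not in cache:
            cache[pairwise] = [featurize_episode(e, pairwise_only=pairwise)
                               for e in episodes]
        return cache[pairwise]

    results: dict[str, dict] = {}
    for variant in variants:
        pairwise = variant == "pairwise"
        physics = variant == "full"
        data = data_for(pairwise)
        accs = []
        for seed in model_seeds:
            core = HPGNNCore(ModelConfig(conv_dims=(16, 32),
                                         ssm=StateSpaceConfig(32, 2),
                                         seed=seed))
            cfg = TrainConfig(max_epochs=max_epochs, pretrain_epochs=2,
                              subseq_len=24, seed=seed)
            weights = LossWeights() if physics else replace(
                LossWeights(), lambda_physics=0.0, lambda_structure=0.0)
            res = train(core, data[:30], data[30:34], cfg, weights)
            accs.append(chimera_accuracy(core, data[34:], res["feature_mu"],
                                         res["feature_sd"]))
        results[variant] = {"accuracies": [float(a) for a in accs],
                            "mean_accuracy": float(np.mean(accs))}
    return results
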