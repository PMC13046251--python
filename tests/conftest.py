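"""Shared fixtures: all synthetic data is generated programmatically with
fixed seeds; the expensive episode collections are session-scoped so the
acceptance-style checks and unit tests share them."""

from __future__ import annotations

import numpy as np
import pytest

from chimerapred.core import MultiChannelSignal, PhaseTrajectory
from chimerapred.episodes import EpisodeSpec, generate_episode, phases_to_signal
from chimerapred.kuramoto import KuramotoParams, simulate_kuramoto


@pytest.fixture(scope="session")
def default_params() -> KuramotoParams:
    return KuramotoParams.chimera_default(seed=42)


@pytest.fixture(scope="session")
def chimera_trajectory(default_params) -> PhaseTrajectory:
    """60 s of the default two-community network in the chimera regime."""
    return simulate_kuramoto(default_params, 60.0, 1.0 / 256.0, seed=7)


@pytest.fixture(scope="session")
def stabilization_signals() -> list[tuple[KuramotoParams, MultiChannelSignal]]:
    """120-s stabilization-segment recordings (chimera regime, noise 0.1)
    for seeds 1..10 — the calibration fixture for band frequencies and
    hypergraph density."""
    out = []
    for seed in range(1, 11):
        params = KuramotoParams.chimera_default(seed=seed)
        traj = simulate_kuramoto(params, 120.0, 1.0 / 256.0, seed=seed)
        out.append((params, phases_to_signal(traj, 1.0, 0.1, seed=1000 + seed)))
    return out


@pytest.fixture(scope="session")
def default_episode():
    """One full default episode (compression 10)."""
    return generate_episode(EpisodeSpec(seed=1))


@pytest.fixture(scope="session")
def default_episodes_20():
    """Default episodes for seeds 1..20 (the chimera-contrast benchmark)."""
    return [generate_episode(EpisodeSpec(seed=s)) for s in range(1, 21)]


@pytest.fixture(scope="session")
def desk_episode():
    """One compact (training-layout) episode."""
    return generate_episode(EpisodeSpec.desk(seed=5))


def stabilization_windows(episode):
    a, b = episode.segment_boundaries["stabilization"]
    return [w for w in episode.window_labels if w.window[0] >= a and w.window[1] <= b]
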