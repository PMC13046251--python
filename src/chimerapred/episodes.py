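"""Synthetic labeled seizure episodes with chimera precursors.

An episode concatenates six dynamical segments of a two-community
Kuramoto-Sakaguchi network:

baseline        weak coupling, both communities incoherent
emergence       coupling ramps up, the delta community gradually locks
stabilization   stable chimera (community 0 locked, community 1 drifting)
transition      coupling rises and the alpha community's frequencies slide
                toward the delta band (approach to global synchrony)
ictal           near-global synchrony at pathological delta frequency
postictal       coupling and frequencies relax back to baseline

Segment durations are expressed in uncompressed (real-time) seconds; the
simulated duration is ``duration / time_compression`` so a multi-hour
progression fits desk compute.  Window labels are always expressed on the
uncompressed minute scale.

Ground-truth labels come from the simulated phases themselves: per window,
per-community Kuramoto order parameters, the > 0.3 synchronization-contrast
rule for the chimera flag, segment membership for the 4-class state, and
minutes-to-onset (capped at 90) for the regression target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MultiChannelSignal, PhaseTrajectory, WindowLabels, WindowPlan, wrap_phase
from .kuramoto import KuramotoParams, integrate_segment

__all__ = [
    "EpisodeSpec",
    "LabeledEpisode",
    "phases_to_signal",
    "generate_episode",
    "ground_truth_labels",
]

SEGMENT_NAMES = ("baseline", "emergence", "stabilization", "transition", "ictal", "postictal")

# state codes per segment: baseline 0; emergence/stabilization/transition
# pre-ictal 1; ictal 2; postictal 3
_SEGMENT_STATE = {
    "baseline": 0,
    "emergence": 1,
    "stabilization": 1,
    "transition": 1,
    "ictal": 2,
    "postictal": 3,
}


@dataclass
class EpisodeSpec:
    """Episode layout and observation model.

    Durations are uncompressed seconds.  Defaults place the pre-ictal
    phases at the midpoints of the reported ranges (emergence 15-25 min,
    stabilization 30-60 min, transition 5-10 min) and make the pre-ictal
    span sum to ~88 min so baseline windows sit beyond the 90-minute
    horizon.
    """

    baseline: float = 30 * 60.0
    emergence: float = 25 * 60.0
    stabilization: float = 55 * 60.0
    transition: float = 8 * 60.0
    ictal: float = 2 * 60.0
    postictal: float = 30 * 60.0
    time_compression: float = 10.0
    sampling_rate: float = 256.0
    noise_sd: float = 0.1
    amplitude: float = 1.0
    baseline_coupling: float = 0.05
    ictal_coupling: float = 1.2
    window: WindowPlan = field(default_factory=WindowPlan)
    seed: int = 42

    def __post_init__(self) -> None:
        for name in SEGMENT_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} duration must be >= 0")
        if self.time_compression <= 0:
            raise ValueError("time_compression must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0 or self.amplitude < 0:
            raise ValueError("noise_sd and amplitude must be >= 0")
        if self.ictal == 0 and self.postictal > 0:
            raise ValueError("zero-length ictal segment with nonzero postictal is invalid")

    def durations(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in SEGMENT_NAMES}

    def simulated_durations(self) -> dict[str, float]:
        return {name: getattr(self, name) / self.time_compression for name in SEGMENT_NAMES}

    @classmethod
    def desk(cls, seed: int = 42) -> "EpisodeSpec":
        """Compact layout for training benchmarks (shorter segments,
        compression 20); labels remain on the uncompressed scale."""
        return cls(
            baseline=16 * 60.0,
            emergence=12 * 60.0,
            stabilization=24 * 60.0,
            transition=6 * 60.0,
            ictal=2 * 60.0,
            postictal=8 * 60.0,
            time_compression=20.0,
            seed=seed,
        )


@dataclass
class LabeledEpisode:
    """A synthetic recording with ground-truth phases and window labels."""

    signal: MultiChannelSignal
    window_labels: list[WindowLabels]
    onset_time: float  # simulated seconds (ictal start); nan if no ictal segment
    segment_boundaries: dict[str, tuple[float, float]]  # simulated seconds
    phases: PhaseTrajectory | None = None
    params: KuramotoParams | None = None
    spec: EpisodeSpec | None = None

    @property
    def n_windows(self) -> int:
        return len(self.window_labels)

    def labels_array(self) -> np.ndarray:
        """(n_windows, 3) array of (ychimera, ystate, ytime)."""
        return np.array([[w.ychimera, w.ystate, w.ytime] for w in self.window_labels])


def phases_to_signal(
    traj: PhaseTrajectory,
    amplitude: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> MultiChannelSignal:
    """Observation model ``x_c(t) = amplitude * sin(theta_c(t)) + eps``.

    ``eps`` is i.i.d. Gaussian with standard deviation ``noise_sd``;
    deterministic given ``seed``.
    """
    if amplitude < 0 or noise_sd < 0:
        raise ValueError("amplitude and noise_sd must be >= 0")
    data = amplitude * np.sin(traj.phases.T)
    if noise_sd > 0:
        if seed is None:
            raise ValueError("seed is required when noise_sd > 0")
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return MultiChannelSignal(data=data, sampling_rate=1.0 / traj.dt, start_time=traj.t0)


def _order_parameter_series(theta: np.ndarray, members: np.ndarray) -> np.ndarray:
    """Instantaneous order parameter of a channel subset, per time sample."""
    z = np.exp(1j * theta[:, members])
    return np.abs(z.mean(axis=1))


def generate_episode(spec: EpisodeSpec, params: KuramotoParams | None = None) -> LabeledEpisode:
    """Simulate one labeled episode under ``spec``.

    The ictal frequency profile collapses every oscillator onto the
    synchronized community's mean frequency (pathological slowing), which —
    combined with the raised ictal coupling — produces near-global synchrony
    that weak baseline coupling cannot.
    """
    if params is None:
        params = KuramotoParams.chimera_default(seed=spec.seed)
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sampling_rate
    sync = params.community == 0
    # chimera-state frequencies: community 0 in tight pathological delta,
    # community 1 in its spread alpha band
    omega_chim = params.omega
    # interictal baseline: every channel at a normal awake (alpha-band)
    # rhythm with the desynchronized community's spread — the pathological
    # delta slowing of community 0 develops during emergence and relaxes
    # after the seizure
    desync_mean = omega_chim[~sync].mean() if np.any(~sync) else omega_chim.mean()
    desync_sd = omega_chim[~sync].std() if np.any(~sync) else 0.1 * desync_mean
    omega_base = omega_chim.copy()
    omega_base[sync] = np.maximum(
        desync_mean + desync_sd * np.clip(rng.standard_normal(sync.sum()), -3, 3),
        1e-3,
    )
    omega_ictal = np.full_like(omega_chim, omega_chim[sync].mean())
    # tiny jitter keeps the ictal state from being a measure-zero fixed point
    omega_ictal = omega_ictal + rng.normal(0.0, 1e-3, size=omega_chim.shape)

    same = params.community[:, None] == params.community[None, :]
    base_mat = np.where(same, 1.0, params.inter_coupling_ratio)

    def kmat(k: float) -> np.ndarray:
        return k * base_mat

    k_base, k_full, k_ictal = spec.baseline_coupling, params.coupling_K, spec.ictal_coupling
    # (omega_start, omega_end, K_start, K_end) per segment
    schedule = {
        "baseline": (omega_base, omega_base, k_base, k_base),
        "emergence": (omega_base, omega_chim, k_base, k_full),
        "stabilization": (omega_chim, omega_chim, k_full, k_full),
        "transition": (omega_chim, omega_ictal, k_full, k_ictal),
        "ictal": (omega_ictal, omega_ictal, k_ictal, k_ictal),
        "postictal": (omega_ictal, omega_base, k_ictal, k_base),
    }

    sim_dur = spec.simulated_durations()
    theta = rng.uniform(-np.pi, np.pi, size=params.n_oscillators)
    pieces: list[np.ndarray] = []
    boundaries: dict[str, tuple[float, float]] = {}
    t_cursor = 0.0
    for name in SEGMENT_NAMES:
        n_steps = int(round(sim_dur[name] / dt))
        if n_steps == 0:
            continue
        om0, om1, ka, kb = schedule[name]
        seg = integrate_segment(theta, om0, om1, kmat(ka), kmat(kb), params.phase_lag_alpha, n_steps, dt)
        theta = seg[-1]
        # drop the duplicated initial row except for the very first segment
        pieces.append(seg if not pieces else seg[1:])
        boundaries[name] = (t_cursor, t_cursor + n_steps * dt)
        t_cursor += n_steps * dt

    phases = np.concatenate(pieces, axis=0)
    traj = PhaseTrajectory(phases=wrap_phase(phases), dt=dt)
    signal = phases_to_signal(
        traj, amplitude=spec.amplitude, noise_sd=spec.noise_sd,
        seed=int(rng.integers(0, 2**31 - 1)) if spec.noise_sd > 0 else None,
    )

    onset = boundaries["ictal"][0] if "ictal" in boundaries else float("nan")
    labels = _ground_truth_labels(traj, params, spec, boundaries, onset)
    return LabeledEpisode(
        signal=signal,
        window_labels=labels,
        onset_time=onset,
        segment_boundaries=boundaries,
        phases=traj,
        params=params,
        spec=spec,
    )


def segment_of(t: float, boundaries: dict[str, tuple[float, float]]) -> str:
    for name, (a, b) in boundaries.items():
        if a <= t < b:
            return name
    # fall back to the last segment for the terminal instant
    return list(boundaries)[-1]


def _ground_truth_labels(
    traj: PhaseTrajectory,
    params: KuramotoParams,
    spec: EpisodeSpec,
    boundaries: dict[str, tuple[float, float]],
    onset: float,
    windows: list[tuple[float, float]] | None = None,
    contrast_threshold: float = 0.3,
) -> list[WindowLabels]:
    theta = traj.phases
    comm0 = np.where(params.community == 0)[0]
    comm1 = np.where(params.community == 1)[0]
    r0 = _order_parameter_series(theta, comm0)
    r1 = _order_parameter_series(theta, comm1)
    if windows is None:
        pairs = spec.window.sample_slices(traj.n_times, spec.sampling_rate)
    else:
        pairs = []
        for (a, b) in windows:
            i0 = int(round((a - traj.t0) * spec.sampling_rate))
            i1 = int(round((b - traj.t0) * spec.sampling_rate))
            pairs.append(((a, b), slice(max(i0, 0), min(i1, traj.n_times))))
    out: list[WindowLabels] = []
    for (a, b), sl in pairs:
        rw = np.array([r0[sl].mean(), r1[sl].mean()])
        contrast = float(rw.max() - rw.min())
        center = 0.5 * (a + b)
        state = _SEGMENT_STATE[segment_of(center, boundaries)]
        if state == 2:
            ytime = 0.0
        elif np.isfinite(onset) and b <= onset:
            # uncompressed minutes to onset, measured from the window end
            ytime = min(90.0, (onset - b) / 60.0 * spec.time_compression)
        else:
            ytime = 90.0 if state == 3 else min(90.0, max(0.0, (onset - b) / 60.0 * spec.time_compression)) if np.isfinite(onset) else 90.0
        out.append(
            WindowLabels(
                window=(a, b),
                cluster_R=rw,
                contrast=contrast,
                ychimera=int(contrast > contrast_threshold),
                ystate=state,
                ytime=float(ytime),
            )
        )
    return out


def ground_truth_labels(
    episode: "LabeledEpisode", windows: list[tuple[float, float]]
) -> np.ndarray:
    """(n_windows, 3) ground-truth ``(ychimera, ystate, ytime)`` at
    arbitrary window boundaries of a generated episode."""
    if episode.phases is None or episode.params is None or episode.spec is None:
        raise ValueError("episode lacks ground-truth phases/params/spec")
    labels = _ground_truth_labels(
        episode.phases, episode.params, episode.spec,
        episode.segment_boundaries, episode.onset_time, windows=windows,
    )
    return np.array([[w.ychimera, w.ystate, w.ytime] for w in labels])
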