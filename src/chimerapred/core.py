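"""Shared containers for multichannel recordings, phase trajectories and windows.

Conventions used throughout the package:

* signals are ``(channels, samples)`` arrays with an explicit sampling rate;
* phase trajectories are ``(time, oscillator)`` arrays in radians wrapped to
  ``[-pi, pi]``;
* analysis windows are half-open intervals ``[start, end)`` in seconds with
  0-based sample indexing — a sample falling exactly on a boundary belongs to
  the later window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultiChannelSignal",
    "PhaseTrajectory",
    "WindowPlan",
    "WindowLabels",
]


@dataclass
class MultiChannelSignal:
    """A sampled multichannel recording (synthetic EEG or real EEG).

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, microvolts or arbitrary synthetic
        units.
    sampling_rate
        Sampling rate in Hz, strictly positive.
    channel_names
        Ordered channel labels; 10-20 montage names for real EEG.
    start_time
        Recording start in seconds.
    """

    data: np.ndarray
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a (channels, samples) matrix")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def copy_with(self, data: np.ndarray, sampling_rate: float | None = None) -> "MultiChannelSignal":
        return MultiChannelSignal(
            data=np.asarray(data, dtype=float),
            sampling_rate=self.sampling_rate if sampling_rate is None else sampling_rate,
            channel_names=list(self.channel_names),
            start_time=self.start_time,
        )


def wrap_phase(theta: np.ndarray) -> np.ndarray:
    """Wrap angles to ``[-pi, pi]``."""
    return np.mod(np.asarray(theta) + np.pi, 2.0 * np.pi) - np.pi


@dataclass
class PhaseTrajectory:
    """Per-channel instantaneous phase in radians.

    ``phases`` is a ``(n_times, n_oscillators)`` matrix wrapped to
    ``[-pi, pi]``; ``dt`` is the step in seconds.  ``guard`` marks a symmetric
    edge interval (seconds) whose samples are unreliable (Hilbert edge
    effects) and should be excluded downstream.
    """

    phases: np.ndarray
    dt: float
    t0: float = 0.0
    guard: float = 0.0

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2 or self.phases.shape[0] < 2:
            raise ValueError("phases must be a (time, oscillator) matrix with >= 2 rows")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.phases = wrap_phase(self.phases)

    @property
    def n_times(self) -> int:
        return self.phases.shape[0]

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_times)

    def unwrapped(self) -> np.ndarray:
        """Phases unwrapped along time (radians, unbounded)."""
        return np.unwrap(self.phases, axis=0)

    def interior_slice(self) -> slice:
        """Sample slice excluding the edge guard on both sides."""
        n_guard = int(round(self.guard / self.dt))
        if 2 * n_guard >= self.n_times:
            raise ValueError("guard interval covers the whole trajectory")
        return slice(n_guard, self.n_times - n_guard if n_guard else self.n_times)


@dataclass
class WindowPlan:
    """Sliding-window layout: half-open ``[start, start + length)`` intervals.

    Defaults follow the 5-second / 50 %-overlap analysis convention; the hop
    is ``length * (1 - overlap)``.
    """

    window_length: float = 5.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if not 0 <= self.overlap < 1:
            raise ValueError("overlap must be in [0, 1)")

    @property
    def hop(self) -> float:
        return self.window_length * (1.0 - self.overlap)

    def boundaries(self, t_start: float, t_end: float) -> list[tuple[float, float]]:
        """All fully contained windows of ``[t_start, t_end)``."""
        out: list[tuple[float, float]] = []
        start = t_start
        # tolerate float jitter at the last window boundary
        while start + self.window_length <= t_end + 1e-9:
            out.append((start, start + self.window_length))
            start += self.hop
        return out

    def sample_slices(self, n_samples: int, sampling_rate: float, t0: float = 0.0) -> list[tuple[tuple[float, float], slice]]:
        """Pair each window with its half-open sample slice."""
        out = []
        for (a, b) in self.boundaries(t0, t0 + n_samples / sampling_rate):
            i0 = int(round((a - t0) * sampling_rate))
            i1 = int(round((b - t0) * sampling_rate))
            out.append(((a, b), slice(i0, min(i1, n_samples))))
        return out


@dataclass
class WindowLabels:
    """Per-window label triple plus cluster order parameters.

    ``ystate`` codes: 0 baseline, 1 pre-ictal (emergence/stabilization/
    transition), 2 ictal, 3 post-ictal.  ``ytime`` is minutes to seizure
    onset in uncompressed (real-time) minutes, capped at 90; ictal windows
    carry 0.
    """

    window: tuple[float, float]
    cluster_R: np.ndarray
    contrast: float
    ychimera: int
    ystate: int = 0
    ytime: float = 90.0

    def __post_init__(self) -> None:
        self.cluster_R = np.asarray(self.cluster_R, dtype=float)
        if not (0.0 <= self.ytime <= 90.0):
            raise ValueError("ytime must lie in [0, 90] minutes")
        if self.ystate not in (0, 1, 2, 3):
            raise ValueError("ystate must be one of {0,1,2,3}")
        if self.ychimera not in (0, 1):
            raise ValueError("ychimera must be binary")
        if self.ystate == 2 and self.ytime != 0.0:
            raise ValueError("ictal windows must carry ytime = 0")
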