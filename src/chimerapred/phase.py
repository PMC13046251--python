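"""Hilbert-transform phase extraction and windowed Phase Locking Values.

The analytic signal ``x + i H[x]`` yields the instantaneous phase
``phi_c(t)`` per channel; the PLV between channels i and j over a window is
``|< exp(i (phi_i - phi_j)) >_t|`` — the modulus of the time-averaged unit
phasor of the phase difference.  A 0.5 s guard at each trajectory edge is
flagged for exclusion because the Hilbert transform is unreliable there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .core import MultiChannelSignal, PhaseTrajectory, WindowPlan

__all__ = ["PLVMatrix", "analytic_phase", "plv_matrix", "EDGE_GUARD_SECONDS"]

EDGE_GUARD_SECONDS = 0.5


@dataclass
class PLVMatrix:
    """Symmetric C x C phase-locking matrix for one window, entries in [0, 1]."""

    values: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PLV values must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("PLV matrix must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("PLV entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def analytic_phase(signal: MultiChannelSignal, guard: float = EDGE_GUARD_SECONDS) -> PhaseTrajectory:
    """Instantaneous phase of each channel via the analytic signal.

    Assumes the signal has been bandpassed (mean-free) upstream.  Raises if
    any channel is identically zero, for which phase is undefined.
    """
    if signal.n_samples < 2:
        raise ValueError("need at least 2 samples per channel")
    power = np.abs(signal.data).max(axis=1)
    dead = np.where(power == 0)[0]
    if dead.size:
        names = ", ".join(signal.channel_names[i] for i in dead)
        raise ValueError(f"phase undefined for all-zero channel(s): {names}")
    analytic = hilbert(signal.data, axis=1)
    phases = np.angle(analytic).T  # (time, channel)
    return PhaseTrajectory(
        phases=phases,
        dt=1.0 / signal.sampling_rate,
        t0=signal.start_time,
        guard=guard,
    )


def plv_matrix(phases: PhaseTrajectory, plan: WindowPlan | None = None) -> list[PLVMatrix]:
    """One PLV matrix per analysis window.

    Windows are laid out over the guard-trimmed interior of the trajectory;
    a window left empty after guard exclusion raises instead of producing a
    silent NaN.
    """
    if plan is None:
        plan = WindowPlan()
    interior = phases.interior_slice()
    theta = phases.phases[interior]
    if theta.shape[0] == 0:
        raise ValueError("no samples remain after guard exclusion")
    t0 = phases.t0 + (interior.start or 0) * phases.dt
    rate = 1.0 / phases.dt
    out: list[PLVMatrix] = []
    for (a, b), sl in WindowPlan(plan.window_length, plan.overlap).sample_slices(theta.shape[0], rate, t0):
        seg = theta[sl]
        if seg.shape[0] == 0:
            raise ValueError(f"window [{a}, {b}) contains no samples")
        z = np.exp(1j * seg)
        # PLV_ij = |mean_t z_i conj(z_j)| computed as one complex Gram matrix
        gram = z.conj().T @ z / seg.shape[0]
        vals = np.abs(gram)
        vals = 0.5 * (vals + vals.T)
        np.fill_diagonal(vals, 1.0)
        out.append(PLVMatrix(values=np.clip(vals, 0.0, 1.0), window=(a, b)))
    if not out:
        raise ValueError("trajectory shorter than one analysis window")
    return out
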