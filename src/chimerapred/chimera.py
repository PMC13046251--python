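"""Chimera statistics: spectral communities, cluster order parameters,
contrast labeling, chimera-index time series, and three-phase segmentation.

A window is chimera-labeled when the synchronization contrast
``max(R_cluster) - min(R_cluster)`` between spectral communities strictly
exceeds 0.3.  The three-phase segmentation (emergence, stabilization,
transition) reconstructs the qualitative pre-seizure progression from the
windowed contrast series; its constants (run length 3, slope 0.01/window,
sync threshold 0.7) are package reconstructions and configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .core import PhaseTrajectory, WindowLabels, WindowPlan
from .phase import PLVMatrix

__all__ = [
    "ClusterAssignment",
    "PhaseSegmentation",
    "spectral_clusters",
    "order_parameter",
    "chimera_label",
    "chimera_index_series",
    "segment_three_phases",
]

logger = logging.getLogger(__name__)

CONTRAST_THRESHOLD = 0.3


@dataclass
class ClusterAssignment:
    """Per-channel community labels with eigengap diagnostics."""

    labels: np.ndarray
    k: int
    eigengaps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        counts = np.bincount(self.labels, minlength=self.k)
        if len(counts) > self.k or np.any(counts[: self.k] == 0):
            raise ValueError("every cluster must be non-empty and labels < k")

    def members(self, cluster: int) -> np.ndarray:
        return np.where(self.labels == cluster)[0]


def spectral_clusters(
    plv: PLVMatrix | np.ndarray, k: int = 2, seed: int = 0
) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering of a similarity matrix.

    Embeds channels in the bottom-k eigenvectors of the symmetric
    normalized Laplacian and clusters the row-normalized embedding with
    seeded k-means.  A disconnected similarity graph is regularized by
    adding 1e-6 uniform similarity (logged).
    """
    sim = plv.values if hasattr(plv, "values") else np.asarray(plv, dtype=float)
    c = sim.shape[0]
    if k < 2 or k > c - 1:
        raise ValueError("need 2 <= k <= C - 1")
    a = sim.copy()
    np.fill_diagonal(a, 0.0)
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        logger.info("disconnected similarity graph; adding 1e-6 uniform similarity")
        a = a + 1e-6
        np.fill_diagonal(a, 0.0)
        deg = a.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    lap = np.eye(c) - d_inv_sqrt[:, None] * a * d_inv_sqrt[None, :]
    evals, evecs = eigh(lap)
    emb = evecs[:, :k]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    emb = emb / norms
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    if len(np.unique(labels)) < k:  # pragma: no cover - k-means safeguard
        km = KMeans(n_clusters=k, random_state=seed + 1, n_init=10)
        labels = km.fit_predict(emb)
    return ClusterAssignment(labels=labels, k=k, eigengaps=np.diff(evals))


def order_parameter(phases: np.ndarray) -> float:
    """Kuramoto order parameter ``R = |sum_j exp(i phi_j)| / N``."""
    phases = np.asarray(phases, dtype=float)
    if phases.size == 0:
        raise ValueError("order parameter of an empty phase set is undefined")
    return float(np.abs(np.exp(1j * phases).mean()))


def chimera_label(
    cluster_R: np.ndarray, threshold: float = CONTRAST_THRESHOLD
) -> tuple[float, int]:
    """Synchronization contrast and chimera flag.

    The inequality is strict; a 1e-12 guard keeps floating-point
    representation error (e.g. 0.65 - 0.35 > 0.3 by 5e-17) from flipping
    boundary cases.
    """
    r = np.asarray(cluster_R, dtype=float)
    if r.size < 2:
        raise ValueError("contrast requires at least 2 clusters")
    contrast = float(r.max() - r.min())
    return contrast, int(contrast > threshold + 1e-12)


def _align_labels(prev: np.ndarray, cur: np.ndarray, k: int) -> np.ndarray:
    """Relabel ``cur`` to maximize overlap with ``prev`` (greedy)."""
    overlap = np.zeros((k, k))
    for a in range(k):
        for b in range(k):
            overlap[a, b] = np.sum((prev == a) & (cur == b))
    mapping = {}
    used_a: set[int] = set()
    used_b: set[int] = set()
    for _ in range(k):
        masked = overlap.copy()
        if used_a:
            masked[list(used_a), :] = -1
        if used_b:
            masked[:, list(used_b)] = -1
        a, b = np.unravel_index(np.argmax(masked), masked.shape)
        mapping[int(b)] = int(a)
        used_a.add(int(a))
        used_b.add(int(b))
    return np.array([mapping[int(v)] for v in cur])


def chimera_index_series(
    phases: PhaseTrajectory,
    plan: WindowPlan | None = None,
    clusters: ClusterAssignment | None = None,
    k: int = 2,
    seed: int = 0,
    threshold: float = CONTRAST_THRESHOLD,
) -> list[WindowLabels]:
    """Per-window cluster order parameters, contrast and chimera flag.

    When ``clusters`` is None the communities are re-estimated every window
    from that window's PLV matrix, with labels aligned to the previous
    window by maximal overlap to prevent spurious label switching.  The
    ``ystate``/``ytime`` fields keep their defaults (0 / 90) — this series
    carries only chimera information.
    """
    if plan is None:
        plan = WindowPlan()
    interior = phases.interior_slice()
    theta = phases.phases[interior]
    t0 = phases.t0 + (interior.start or 0) * phases.dt
    rate = 1.0 / phases.dt
    out: list[WindowLabels] = []
    prev_labels: np.ndarray | None = None
    for (a, b), sl in plan.sample_slices(theta.shape[0], rate, t0):
        seg = theta[sl]
        if clusters is None:
            z = np.exp(1j * seg)
            gram = np.abs(z.conj().T @ z / seg.shape[0])
            gram = 0.5 * (gram + gram.T)
            np.fill_diagonal(gram, 1.0)
            assign = spectral_clusters(np.clip(gram, 0, 1), k=k, seed=seed)
            labels = assign.labels
            if prev_labels is not None:
                labels = _align_labels(prev_labels, labels, k)
            prev_labels = labels
        else:
            labels = clusters.labels
        r = np.empty(k)
        for cl in range(k):
            members = np.where(labels == cl)[0]
            z = np.exp(1j * seg[:, members])
            r[cl] = float(np.abs(z.mean(axis=1)).mean())
        contrast, flag = chimera_label(r, threshold)
        out.append(
            WindowLabels(window=(a, b), cluster_R=r, contrast=contrast, ychimera=flag)
        )
    return out


@dataclass
class PhaseSegmentation:
    """Detected onsets (seconds) of the pre-seizure chimera phases.

    Any field may be None when the corresponding phase was not found;
    ``detected`` is False when no chimera-positive run exists at all.
    """

    emergence_onset: float | None
    stabilization_onset: float | None
    transition_onset: float | None
    detected: bool


def segment_three_phases(
    series: list[WindowLabels],
    run_length: int = 3,
    contrast_level: float = CONTRAST_THRESHOLD,
    slope_tolerance: float = 0.01,
    sync_threshold: float = 0.7,
    smooth_windows: int = 5,
) -> PhaseSegmentation:
    """Reconstruct emergence / stabilization / transition onsets.

    * emergence: first window of the earliest run of ``run_length``
      consecutive chimera-positive windows;
    * stabilization: first window where the centered moving average of the
      contrast exceeds ``contrast_level`` with slope magnitude below
      ``slope_tolerance`` per window;
    * transition: first window after stabilization where the least
      synchronized cluster's order parameter rises above
      ``sync_threshold`` (approach to global synchrony).
    """
    if len(series) < 10:
        raise ValueError("need at least 10 windows to segment phases")
    flags = np.array([w.ychimera for w in series])
    contrast = np.array([w.contrast for w in series])
    min_r = np.array([w.cluster_R.min() for w in series])
    starts = [w.window[0] for w in series]

    emergence_idx = None
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run == run_length:
            emergence_idx = i - run_length + 1
            break
    if emergence_idx is None:
        return PhaseSegmentation(None, None, None, detected=False)

    half = smooth_windows // 2
    kernel = np.ones(smooth_windows) / smooth_windows
    smoothed = np.convolve(contrast, kernel, mode="same")
    slope = np.gradient(smoothed)
    stab_idx = None
    for i in range(emergence_idx + 1, len(series) - half):
        if smoothed[i] > contrast_level and abs(slope[i]) < slope_tolerance:
            stab_idx = i
            break

    trans_idx = None
    if stab_idx is not None:
        for i in range(stab_idx + 1, len(series)):
            if min_r[i] > sync_threshold:
                trans_idx = i
                break

    return PhaseSegmentation(
        emergence_onset=starts[emergence_idx],
        stabilization_onset=starts[stab_idx] if stab_idx is not None else None,
        transition_onset=starts[trans_idx] if trans_idx is not None else None,
        detected=True,
    )
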