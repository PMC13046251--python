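"""Hypergraph construction: channel features, adjacency refinement, and
3-clique hyperedge detection.

A hyperedge is an electrode triplet ``{i, j, k}`` whose three pairwise
connectivity entries all strictly exceed the threshold ``tau`` (default
0.65) — a coherently oscillating group.  The operating range for hypergraph
density is 10-30 % of the ``C choose 3`` possible triplets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import signal as sps

from .core import MultiChannelSignal
from .phase import PLVMatrix

__all__ = [
    "AdjacencyMatrix",
    "ChannelFeatureVector",
    "Hypergraph",
    "AdjacencyRefiner",
    "channel_features",
    "features_matrix",
    "refine_adjacency",
    "detect_3cliques",
    "hyperedge_density",
    "incidence_matrix",
    "write_hypergraph",
    "read_hypergraph",
]

logger = logging.getLogger(__name__)

DEFAULT_TAU = 0.65

BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

FEATURE_NAMES = (
    "mean", "variance", "skewness",
    "delta", "theta", "alpha", "beta", "gamma",
    "spectral_entropy",
)


@dataclass
class AdjacencyMatrix:
    """Symmetric C x C connectivity with entries in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("adjacency must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("adjacency entries must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ChannelFeatureVector:
    """Nine per-channel descriptors: temporal statistics, canonical band
    power fractions, and spectral (Shannon) entropy of the periodogram."""

    channel: int
    mean: float
    variance: float
    skewness: float
    band_powers: dict[str, float]
    spectral_entropy: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.mean, self.variance, self.skewness]
            + [self.band_powers[b] for b in BANDS]
            + [self.spectral_entropy]
        )


def channel_features(
    signal: MultiChannelSignal, window: tuple[float, float] | None = None
) -> list[ChannelFeatureVector]:
    """Per-channel feature vectors over ``window`` (whole signal if None).

    Band powers come from a Welch periodogram (2 s segments, 50 % overlap)
    and are expressed as fractions of total power; spectral entropy is the
    Shannon entropy (nats) of the normalized periodogram.  Zero-variance
    channels report skewness 0 with a degenerate flag.
    """
    rate = signal.sampling_rate
    if window is None:
        data = signal.data
    else:
        a, b = window
        i0 = int(round((a - signal.start_time) * rate))
        i1 = int(round((b - signal.start_time) * rate))
        data = signal.data[:, i0:i1]
    if data.shape[1] < 2 * rate:
        raise ValueError("window must span at least 2 seconds for stable spectra")
    nperseg = min(int(2 * rate), data.shape[1])
    freqs, psd = sps.welch(data, fs=rate, nperseg=nperseg, noverlap=nperseg // 2, axis=1)
    out: list[ChannelFeatureVector] = []
    for c in range(data.shape[0]):
        x = data[c]
        mu = float(x.mean())
        var = float(x.var())
        degenerate = var == 0.0
        if degenerate:
            skew = 0.0
        else:
            skew = float(((x - mu) ** 3).mean() / var ** 1.5)
        p = psd[c]
        total = np.trapezoid(p[freqs > 0], freqs[freqs > 0])
        bands = {}
        for name, (lo, hi) in BANDS.items():
            m = (freqs >= lo) & (freqs < hi)
            bands[name] = float(np.trapezoid(p[m], freqs[m]) / total) if total > 0 else 0.0
        pn = p[p > 0]
        if pn.size and pn.sum() > 0:
            q = pn / pn.sum()
            entropy = float(-(q * np.log(q)).sum())
        else:
            entropy = 0.0
        out.append(
            ChannelFeatureVector(
                channel=c, mean=mu, variance=var, skewness=skew,
                band_powers=bands, spectral_entropy=entropy, degenerate=degenerate,
            )
        )
    return out


def features_matrix(features: list[ChannelFeatureVector]) -> np.ndarray:
    """(C, 9) stacked feature matrix."""
    return np.stack([f.as_array() for f in features])


class AdjacencyRefiner:
    """3-layer MLP mapping concatenated channel features to C^2 attention.

    Layer widths follow the 128-64-C^2 schedule.  Weights are plain NumPy
    arrays; an untrained (freshly seeded) instance produces near-uniform
    attention.  Use ``refiner=None`` in :func:`refine_adjacency` for the
    strict identity (PLV pass-through) mode.
    """

    def __init__(self, n_channels: int, n_features: int = 9, seed: int = 42):
        rng = np.random.default_rng(seed)
        dims = [n_channels * n_features, 128, 64, n_channels * n_channels]
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            self.weights.append(rng.normal(0.0, 0.05 / np.sqrt(d_in), size=(d_in, d_out)))
            self.biases.append(np.zeros(d_out))
        self.n_channels = n_channels

    def __call__(self, features: list[ChannelFeatureVector] | np.ndarray) -> np.ndarray:
        x = features_matrix(features) if isinstance(features, list) else np.asarray(features)
        h = x.reshape(-1)
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            h = h @ w + b
            if i < len(self.weights) - 1:
                h = np.tanh(h)
        att = h.reshape(self.n_channels, self.n_channels)
        # attention scores in [0, 1]
        return 1.0 / (1.0 + np.exp(-att))


def _row_softmax(m: np.ndarray) -> np.ndarray:
    e = np.exp(m - m.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


def refine_adjacency(
    features: list[ChannelFeatureVector] | np.ndarray | None,
    plv: PLVMatrix | AdjacencyMatrix | np.ndarray,
    refiner: AdjacencyRefiner | None = None,
) -> AdjacencyMatrix:
    """Feature-conditioned refinement of a PLV matrix.

    With a refiner: attention scores are multiplied elementwise with the
    PLV matrix, passed through a row-wise softmax, symmetrized as
    ``(M + M^T) / 2`` and max-normalized back to [0, 1] so the clique
    threshold keeps its meaning (a row softmax over C entries would
    otherwise cap values near 1/C).

    Identity mode (``refiner=None``) passes the PLV matrix through
    unchanged, trivially preserving its entry ranking.
    """
    vals = plv.values if hasattr(plv, "values") else np.asarray(plv, dtype=float)
    if refiner is None:
        return AdjacencyMatrix(values=vals.copy())
    att = refiner(features) if callable(refiner) else np.asarray(refiner, dtype=float)
    if att.shape != vals.shape:
        raise ValueError(f"attention shape {att.shape} does not match adjacency {vals.shape}")
    m = _row_softmax(att * vals)
    m = 0.5 * (m + m.T)
    top = m.max()
    if top > 0:
        m = m / top
    return AdjacencyMatrix(values=np.clip(m, 0.0, 1.0))


@dataclass
class Hypergraph:
    """Channel nodes plus 3-node hyperedges with optional weights."""

    nodes: list[int]
    hyperedges: list[tuple[int, int, int]]
    edge_weights: np.ndarray | None = None
    source_adjacency: AdjacencyMatrix | None = None
    tau: float = DEFAULT_TAU
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        seen = set()
        for e in self.hyperedges:
            if len(set(e)) != 3:
                raise ValueError(f"hyperedge {e} must have 3 distinct nodes")
            key = tuple(sorted(e))
            if key in seen:
                raise ValueError(f"duplicate hyperedge {e}")
            seen.add(key)
        if self.edge_weights is not None:
            self.edge_weights = np.asarray(self.edge_weights, dtype=float)
            if self.edge_weights.shape != (len(self.hyperedges),):
                raise ValueError("one weight per hyperedge required")
            if self.edge_weights.size and (
                self.edge_weights.min() < 0 or self.edge_weights.max() > 1
            ):
                raise ValueError("weights must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)


def detect_3cliques(
    adjacency: AdjacencyMatrix | np.ndarray,
    tau: float = DEFAULT_TAU,
    window: tuple[float, float] | None = None,
) -> Hypergraph:
    """Exhaustive 3-clique enumeration at strict threshold ``tau``.

    A triplet is a hyperedge iff all three pairwise entries strictly exceed
    ``tau``; enumeration order is the sorted lexicographic order of the
    triplets and does not depend on input ordering.
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    adj = adjacency if isinstance(adjacency, AdjacencyMatrix) else AdjacencyMatrix(np.asarray(adjacency, dtype=float))
    vals = adj.values
    c = adj.n_channels
    above = vals > tau
    edges: list[tuple[int, int, int]] = []
    if c >= 3:
        triplets = np.array(list(combinations(range(c), 3)))
        i, j, k = triplets[:, 0], triplets[:, 1], triplets[:, 2]
        keep = above[i, j] & above[j, k] & above[i, k]
        edges = [tuple(t) for t in triplets[keep]]
    return Hypergraph(
        nodes=list(range(c)),
        hyperedges=edges,
        edge_weights=None,
        source_adjacency=adj,
        tau=tau,
        window=window,
    )


def hyperedge_density(h: Hypergraph) -> float:
    """Detected hyperedges over ``C choose 3`` possible triplets."""
    if h.n_nodes < 3:
        raise ValueError("density needs at least 3 nodes")
    return h.n_hyperedges / comb(h.n_nodes, 3)


def incidence_matrix(h: Hypergraph) -> np.ndarray:
    """(n_hyperedges, n_nodes) binary incidence matrix."""
    inc = np.zeros((h.n_hyperedges, h.n_nodes))
    node_pos = {n: p for p, n in enumerate(h.nodes)}
    for row, e in enumerate(h.hyperedges):
        for n in e:
            inc[row, node_pos[n]] = 1.0
    return inc


def write_hypergraph(h: Hypergraph, path: str) -> None:
    """Line-oriented text export: header, then one ``i j k weight`` line."""
    with open(path, "w") as fh:
        win = f"{h.window[0]} {h.window[1]}" if h.window else "nan nan"
        fh.write(f"# chimerapred hypergraph C={h.n_nodes} tau={h.tau} window={win}\n")
        for idx, e in enumerate(h.hyperedges):
            w = h.edge_weights[idx] if h.edge_weights is not None else 1.0
            fh.write(f"{e[0]} {e[1]} {e[2]} {w:.6g}\n")


def read_hypergraph(path: str) -> Hypergraph:
    with open(path) as fh:
        header = fh.readline().strip()
        parts = dict(
            tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
        )
        c = int(parts["C"])
        tau = float(parts["tau"])
        edges, weights = [], []
        for line in fh:
            i, j, k, w = line.split()
            edges.append((int(i), int(j), int(k)))
            weights.append(float(w))
    return Hypergraph(
        nodes=list(range(c)),
        hyperedges=edges,
        edge_weights=np.array(weights) if weights else None,
        tau=tau,
    )
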