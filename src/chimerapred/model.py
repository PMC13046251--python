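"""Physics-informed hypergraph network: spatial hypergraph convolutions,
selective state-space temporal blocks, physics extraction heads and
multi-task prediction heads.

Architecture outline, per 5-second window:

1. per-channel feature vectors are projected and passed through
   hypergraph convolution layers whose message passing aggregates over
   hyperedges (electrode triplets) with attention-weighted pooling;
2. node embeddings are mean-pooled into one window embedding ``z_t``;
3. the window sequence runs through selective state-space (Mamba-style)
   blocks: per step, a diagonal stable state matrix ``A(z_t)`` and gating
   projections are computed from the input, discretized by zero-order
   hold with a learnable step ``Delta``;
4. the final embeddings feed a chimera head (sigmoid), a 4-class state
   head (softmax), a time-to-seizure head (ReLU) and a physics readout
   producing per-channel phases, positive frequencies, a coupling in
   [0, 1] and a phase lag in [0, pi/2].

Desk-scale defaults (16->32 convolutions, state dim 32, 2 blocks) keep a
full forward pass on a 23-channel episode interactive on one CPU; the
full-scale schedule (64->128->256, dim 256, 4 blocks) is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, softmax, stack
from .hypergraph import Hypergraph, incidence_matrix

__all__ = [
    "ModelConfig",
    "StateSpaceConfig",
    "PhysicsReadout",
    "TaskOutputs",
    "Linear",
    "LayerNorm",
    "BatchNorm",
    "HypergraphConvLayer",
    "MambaBlock",
    "PhysicsHead",
    "PredictionHeads",
    "HPGNNCore",
    "hypergraph_conv",
    "mamba_block",
]


# ---------------------------------------------------------------------------
# configuration


@dataclass
class StateSpaceConfig:
    """Selective state-space block configuration.

    ``state_dim`` defaults to the desk-reducible 32 (full scale 256);
    ``n_blocks`` to 2 (full scale 4).  ``log_delta_init`` is the initial
    learnable log step size, exp(log_delta) = 0.01.
    """

    state_dim: int = 32
    n_blocks: int = 2
    log_delta_init: float = float(np.log(0.01))

    def __post_init__(self) -> None:
        if self.state_dim < 1 or self.n_blocks < 1:
            raise ValueError("state_dim and n_blocks must be >= 1")


@dataclass
class ModelConfig:
    """Flat configuration namespace for the full network."""

    n_channels: int = 23
    n_features: int = 9
    conv_dims: tuple[int, ...] = (16, 32)
    ssm: StateSpaceConfig = field(default_factory=StateSpaceConfig)
    dropout: float = 0.3
    attention_hidden: int = 16
    seed: int = 42

    @classmethod
    def full_scale(cls, n_channels: int = 23) -> "ModelConfig":
        return cls(
            n_channels=n_channels,
            conv_dims=(64, 128, 256),
            ssm=StateSpaceConfig(state_dim=256, n_blocks=4),
        )


@dataclass
class PhysicsReadout:
    """Kuramoto-interpretable outputs; ranges hold by activation design."""

    phases: np.ndarray          # (..., C) in [-pi, pi]
    frequencies: np.ndarray     # (..., C) positive, rad/s
    coupling_K: np.ndarray      # (...,) in [0, 1]
    phase_lag_alpha: np.ndarray  # (...,) in [0, pi/2]


@dataclass
class TaskOutputs:
    """Multi-task predictions per window."""

    p_chimera: np.ndarray       # (...,) in [0, 1]
    state_probs: np.ndarray     # (..., 4) rows on the simplex
    time_estimate: np.ndarray   # (...,) minutes >= 0


# ---------------------------------------------------------------------------
# layers


class Module:
    """Tiny parameter-container base."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        out.append(item)
        return out

    def state_arrays(self) -> list[np.ndarray]:
        """All arrays that define the module (parameters + running stats)."""
        arrays = [p.data for p in self.parameters()]
        for m in self._submodules():
            if isinstance(m, BatchNorm):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def _submodules(self) -> list["Module"]:
        subs: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                subs.extend(v._submodules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        subs.extend(item._submodules())
        return subs


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float | None = None):
        s = scale if scale is not None else 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.normal(0.0, s, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta


class BatchNorm(Module):
    """1-D batch normalization with running statistics.

    Training mode requires a batch of at least 2 rows (single-row batch
    statistics are degenerate); evaluation mode uses the running moments.
    """

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        if train:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization in train mode needs a batch of >= 2 rows"
                )
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data[0]
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data[0]
            return self.gamma * (xc / (var + self.eps).sqrt()) + self.beta
        xc = x - Tensor(self.running_mean)
        return self.gamma * (xc / Tensor(self.running_var + self.eps).sqrt()) + self.beta


def _dropout(x: Tensor, p: float, train: bool, rng: np.random.Generator) -> Tensor:
    if not train or p <= 0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# hypergraph convolution


def pooling_incidence(h: Hypergraph | np.ndarray) -> np.ndarray:
    """(E, C) incidence with rows normalized by edge size (mean pooling)."""
    inc = incidence_matrix(h) if isinstance(h, Hypergraph) else np.asarray(h, dtype=float)
    sizes = inc.sum(axis=1, keepdims=True)
    sizes[sizes == 0] = 1.0
    return inc / sizes


class HypergraphConvLayer(Module):
    """One attention-weighted hypergraph message-passing layer.

    Per node i: pool member embeddings of every hyperedge containing i
    (mean), score each pooled embedding with a 2-layer attention MLP,
    softmax-normalize the scores over i's hyperedges, sum, concatenate
    with h_i, apply the linear map, ELU, layer normalization, a residual
    projection and dropout.  Nodes in no hyperedge receive a zero
    aggregate.
    """

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 att_hidden: int = 16, dropout: float = 0.3):
        self.lin = Linear(2 * d_in, d_out, rng)
        self.att1 = Linear(d_in, att_hidden, rng)
        self.att2 = Linear(att_hidden, 1, rng)
        self.norm = LayerNorm(d_out)
        self.res = Linear(d_in, d_out, rng) if d_in != d_out else None
        self.dropout = dropout

    def attention_weights(self, inc_norm: np.ndarray, h: Tensor) -> Tensor | None:
        """(..., E, C) per-node-normalized attention over incident edges.

        ``inc_norm`` may be a single (E, C) window or a padded
        (T, E_max, C) batch; padded all-zero rows contribute nothing.
        """
        if inc_norm.shape[-2] == 0:
            return None
        pooled = Tensor(inc_norm) @ h                       # (..., E, d_in)
        scores = self.att2(self.att1(pooled).tanh())        # (..., E, 1)
        member = (inc_norm > 0).astype(float)               # (..., E, C)
        e = (scores - float(scores.data.max())).exp()
        numer = Tensor(member) * e                          # (..., E, C)
        denom = numer.sum(axis=-2, keepdims=True)
        denom = denom + Tensor((denom.data == 0).astype(float))
        return numer / denom

    def __call__(self, inc_norm: np.ndarray, h: Tensor, train: bool,
                 rng: np.random.Generator) -> Tensor:
        if inc_norm.shape[-2] == 0:
            agg = Tensor(np.zeros(h.shape))
        else:
            pooled = Tensor(inc_norm) @ h                    # (..., E, d_in)
            alpha = self.attention_weights(inc_norm, h)
            agg = alpha.swapaxes(-2, -1) @ pooled            # (..., C, d_in)
        out = self.lin(concat([h, agg], axis=-1)).elu()
        out = self.norm(out)
        out = out + (self.res(h) if self.res is not None else h)
        return _dropout(out, self.dropout, train, rng)


def hypergraph_conv(h: Hypergraph, emb: np.ndarray | Tensor,
                    layer: HypergraphConvLayer, train: bool = False,
                    seed: int = 0) -> Tensor:
    """Functional wrapper: one convolution of ``emb`` over ``h``."""
    x = emb if isinstance(emb, Tensor) else Tensor(emb)
    if x.shape[0] != h.n_nodes:
        raise ValueError("embedding rows must match hypergraph node count")
    return layer(pooling_incidence(h), x, train, np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# selective state-space block


class MambaBlock(Module):
    """Input-selective linear state-space recurrence, zero-order hold.

    The continuous system ``h' = A(z) h + B(z) z`` with input-dependent
    diagonal ``A(z) = -softplus(Wa z + ba)`` (stability by construction)
    is discretized with step ``Delta = exp(log_delta)``:

        Abar_t = exp(Delta * A_t)
        h_t    = Abar_t * h_{t-1} + ((Abar_t - 1) / A_t) * u_t,  h_0 = 0
        y_t    = C(z_t) * h_t + d * z_t

    where ``u_t = Wb z_t + bb`` is the input projection, ``C(z_t) =
    Wc z_t + bc`` a selective output gate and ``d`` a learned diagonal
    skip.  The ``(Abar - 1)/A`` zero-order-hold factor uses a series
    fallback for small ``|A| Delta``.  Complexity is linear in sequence
    length.
    """

    def __init__(self, d: int, rng: np.random.Generator, log_delta_init: float = float(np.log(0.01))):
        self.wa = Linear(d, d, rng, scale=0.1 / np.sqrt(d))
        self.wb = Linear(d, d, rng)
        self.wc = Linear(d, d, rng, scale=0.1 / np.sqrt(d))
        self.d_skip = Tensor(np.ones(d), requires_grad=True)
        self.log_delta = Tensor(np.array([log_delta_init]), requires_grad=True)
        self.dim = d

    def __call__(self, z: Tensor) -> Tensor:
        t_len = z.shape[0]
        delta = self.log_delta.exp()
        a = -self.wa(z).softplus()          # (T, d), strictly negative
        u = self.wb(z)                      # (T, d)
        c_gate = self.wc(z)                 # (T, d)
        abar = (a * delta).exp()            # (T, d) in (0, 1)
        # zero-order hold input factor (Abar - 1)/A with small-|A| series
        ad = (a * delta).data
        small = np.abs(ad) < 1e-6
        pick = Tensor(small.astype(float))
        # keep the denominator away from 0 where the series branch is used
        safe_a = a - pick
        bfac = ((abar - 1.0) / safe_a) * (1.0 - pick)
        if small.any():
            series = delta * (1.0 + 0.5 * (a * delta))
            bfac = bfac + series * pick
        h = Tensor(np.zeros(self.dim))
        ys: list[Tensor] = []
        for t in range(t_len):
            h = abar[t] * h + bfac[t] * u[t]
            if not np.all(np.isfinite(h.data)):
                raise FloatingPointError(f"state-space recurrence diverged at step {t}")
            ys.append(c_gate[t] * h + self.d_skip * z[t])
        return stack(ys, axis=0)


def mamba_block(z: np.ndarray | Tensor, cfg: StateSpaceConfig | None = None,
                block: MambaBlock | None = None, seed: int = 0) -> Tensor:
    """Functional wrapper: run one block over a (T, d) sequence."""
    zt = z if isinstance(z, Tensor) else Tensor(z)
    if zt.ndim != 2 or zt.shape[0] < 1:
        raise ValueError("sequence must be (T >= 1, d)")
    if block is None:
        cfg = cfg or StateSpaceConfig(state_dim=zt.shape[1])
        block = MambaBlock(zt.shape[1], np.random.default_rng(seed), cfg.log_delta_init)
    return block(zt)


# ---------------------------------------------------------------------------
# heads


class PhysicsHead(Module):
    """Physics extraction: phases (pi*tanh), frequencies (softplus),
    coupling (sigmoid) and phase lag ((pi/2)*sigmoid).

    Biases are initialized so a freshly constructed head outputs near the
    theoretical chimera operating point (K ~ 0.7, alpha ~ pi/6) on random
    inputs; weights start small so the initial spread is narrow.
    """

    def __init__(self, d: int, n_channels: int, rng: np.random.Generator,
                 omega_init_hz: float = 0.05):
        small = 0.01 / np.sqrt(d)
        self.phase = Linear(d, n_channels, rng, scale=1.0 / np.sqrt(d))
        self.freq = Linear(d, n_channels, rng, scale=small)
        self.coupling = Linear(d, 1, rng, scale=small)
        self.lag = Linear(d, 1, rng, scale=small)
        # sigmoid^{-1}(0.7) and sigmoid^{-1}((pi/6)/(pi/2)) = logit(1/3)
        self.coupling.bias.data[:] = np.log(0.7 / 0.3)
        self.lag.bias.data[:] = np.log((1 / 3) / (2 / 3))
        # softplus^{-1}(2 pi f); the readout phases are per-window (slow)
        # phases, so the frequency scale starts well below the carrier bands
        self.freq.bias.data[:] = np.log(np.expm1(2 * np.pi * omega_init_hz))

    def tensors(self, z: Tensor) -> dict[str, Tensor]:
        return {
            "phases": z_tanh_pi(self.phase(z)),
            "frequencies": self.freq(z).softplus(),
            "coupling_K": self.coupling(z).sigmoid(),
            "phase_lag_alpha": self.lag(z).sigmoid() * (np.pi / 2),
        }

    def __call__(self, z: Tensor) -> PhysicsReadout:
        t = self.tensors(z)
        squeeze = lambda a: a.data[..., 0] if a.data.shape[-1] == 1 else a.data
        return PhysicsReadout(
            phases=t["phases"].data,
            frequencies=t["frequencies"].data,
            coupling_K=squeeze(t["coupling_K"]),
            phase_lag_alpha=squeeze(t["phase_lag_alpha"]),
        )


def z_tanh_pi(x: Tensor) -> Tensor:
    return x.tanh() * np.pi


class PredictionHeads(Module):
    """Chimera (2 FC, sigmoid), state (3 FC, softmax), time (2 FC, ReLU)
    heads with batch normalization and dropout 0.3."""

    def __init__(self, d: int, rng: np.random.Generator, dropout: float = 0.3):
        h1, h2 = max(d // 2, 4), max(d // 4, 4)
        self.chim1, self.chim_bn = Linear(d, h1, rng), BatchNorm(h1)
        self.chim2 = Linear(h1, 1, rng)
        self.st1, self.st_bn1 = Linear(d, h1, rng), BatchNorm(h1)
        self.st2, self.st_bn2 = Linear(h1, h2, rng), BatchNorm(h2)
        self.st3 = Linear(h2, 4, rng)
        self.tm1, self.tm_bn = Linear(d, h1, rng), BatchNorm(h1)
        self.tm2 = Linear(h1, 1, rng)
        self.dropout = dropout

    def tensors(self, z: Tensor, train: bool, rng: np.random.Generator) -> dict[str, Tensor]:
        c = _dropout(self.chim_bn(self.chim1(z).relu(), train), self.dropout, train, rng)
        p_chimera = self.chim2(c).sigmoid()
        s = _dropout(self.st_bn1(self.st1(z).relu(), train), self.dropout, train, rng)
        s = _dropout(self.st_bn2(self.st2(s).relu(), train), self.dropout, train, rng)
        state = softmax(self.st3(s), axis=-1)
        t = _dropout(self.tm_bn(self.tm1(z).relu(), train), self.dropout, train, rng)
        time_est = self.tm2(t).relu()
        return {"p_chimera": p_chimera, "state_probs": state, "time_estimate": time_est}

    def __call__(self, z: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> TaskOutputs:
        rng = rng or np.random.default_rng(0)
        t = self.tensors(z, train, rng)
        return TaskOutputs(
            p_chimera=t["p_chimera"].data[..., 0],
            state_probs=t["state_probs"].data,
            time_estimate=t["time_estimate"].data[..., 0],
        )


# ---------------------------------------------------------------------------
# full network


class HPGNNCore(Module):
    """Shared encoder + all heads; operates on per-window incidence
    matrices and channel-feature matrices.

    Convolution parameters are shared across windows; per-window node
    embeddings are mean-pooled into the window embedding sequence, which
    the state-space blocks process in order.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        self.input_proj = Linear(cfg.n_features, cfg.conv_dims[0], rng)
        self.convs = [
            HypergraphConvLayer(d_in, d_out, rng, cfg.attention_hidden, cfg.dropout)
            for d_in, d_out in zip(cfg.conv_dims[:-1], cfg.conv_dims[1:])
        ]
        d_embed = cfg.conv_dims[-1]
        self.to_state = Linear(d_embed, cfg.ssm.state_dim, rng)
        self.blocks = [
            MambaBlock(cfg.ssm.state_dim, rng, cfg.ssm.log_delta_init)
            for _ in range(cfg.ssm.n_blocks)
        ]
        self.block_norms = [LayerNorm(cfg.ssm.state_dim) for _ in self.blocks]
        self.heads = PredictionHeads(cfg.ssm.state_dim, rng, cfg.dropout)
        self.physics = PhysicsHead(cfg.ssm.state_dim, cfg.n_channels, rng)
        # masked-pretraining machinery
        self.mask_token = Tensor(rng.normal(0, 0.1, size=cfg.n_features), requires_grad=True)
        self.recon_feat = Linear(d_embed, cfg.n_features, rng)
        self.recon_adj = Linear(d_embed, cfg.n_channels, rng)

    def encode_window(self, inc_norm: np.ndarray, feats: Tensor | np.ndarray,
                      train: bool, rng: np.random.Generator) -> Tensor:
        """(C, n_features) -> (C, d_embed) node embeddings for one window."""
        h = self.input_proj(feats if isinstance(feats, Tensor) else Tensor(feats))
        for conv in self.convs:
            h = conv(inc_norm, h, train, rng)
        return h

    @staticmethod
    def pad_incidences(incidences: list[np.ndarray], n_channels: int) -> np.ndarray:
        """Stack per-window incidence matrices into (T, E_max, C) with
        zero-row padding (padded rows are inert in the convolution)."""
        e_max = max((inc.shape[0] for inc in incidences), default=0)
        out = np.zeros((len(incidences), max(e_max, 1), n_channels))
        for t, inc in enumerate(incidences):
            if inc.shape[0]:
                out[t, : inc.shape[0]] = inc
        return out

    def encode_sequence(self, incidences: list[np.ndarray] | np.ndarray,
                        features: np.ndarray, train: bool,
                        rng: np.random.Generator) -> Tensor:
        """Window sequence -> (T, state_dim) temporal embeddings."""
        if isinstance(incidences, list):
            incidences = self.pad_incidences(incidences, features.shape[1])
        h = self.input_proj(Tensor(features))               # (T, C, d0)
        for conv in self.convs:
            h = conv(incidences, h, train, rng)
        z = self.to_state(h.mean(axis=1))                   # (T, state_dim)
        for norm, block in zip(self.block_norms, self.blocks):
            z = z + block(norm(z))
        return z

    def forward_tensors(self, incidences: list[np.ndarray], features: np.ndarray,
                        train: bool = False, seed: int = 0) -> dict[str, Tensor]:
        rng = np.random.default_rng(seed)
        z = self.encode_sequence(incidences, features, train, rng)
        out = self.heads.tensors(z, train, rng)
        out.update(self.physics.tensors(z))
        out["embeddings"] = z
        return out

    def forward(self, incidences: list[np.ndarray], features: np.ndarray,
                train: bool = False, seed: int = 0) -> tuple[TaskOutputs, PhysicsReadout]:
        t = self.forward_tensors(incidences, features, train, seed)
        tasks = TaskOutputs(
            p_chimera=t["p_chimera"].data[:, 0],
            state_probs=t["state_probs"].data,
            time_estimate=t["time_estimate"].data[:, 0],
        )
        phys = PhysicsReadout(
            phases=t["phases"].data,
            frequencies=t["frequencies"].data,
            coupling_K=t["coupling_K"].data[:, 0],
            phase_lag_alpha=t["phase_lag_alpha"].data[:, 0],
        )
        return tasks, phys
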