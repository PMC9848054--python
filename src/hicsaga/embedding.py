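"""Second-order-proximity node embedding of the contact graph.

Each bin (node) ``i`` gets an embedding vector ``u_i`` and a context
vector ``u'_i``. A softmax over context vectors,

    p2(j | i) = exp(u'_j . u_i) / sum_k exp(u'_k . u_i),

models the probability that node ``j`` appears in the neighbourhood of
node ``i``. Training pulls p2(.|i) toward the empirical neighbour
distribution  p̂2(j|i) = w_ij / d_i  with node weights equal to degree,
which collapses the weighted KL objective to

    O2 = - sum_{(i,j) in E} w_ij log p2(j | i).

Bins with similar genome-wide interaction profiles — the defining
property of a chromatin (sub)compartment — end up close in embedding
space even if they never touch directly.

The softmax is intractable at genome scale, so training uses edge
sampling (edges drawn proportionally to weight via an alias table) with
negative sampling from a degree^0.75 noise distribution, single
threaded and bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.special import logsumexp

from .core import BinnedGenome, ContactGraph, FeatureMatrix


@dataclass
class TrainConfig:
    dim: int = 8
    negatives: int = 5
    samples: int | None = None  # default max(100 * |E|, 1_000_000)
    rho0: float = 0.025  # initial learning rate, linear decay
    rho_min_frac: float = 1e-4  # floor = rho0 * rho_min_frac
    noise_exponent: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if self.dim <= 0:
            raise ValueError("dim must be positive")
        if self.negatives <= 0:
            raise ValueError("negatives must be positive")
        if self.samples is not None and self.samples <= 0:
            raise ValueError("samples must be positive")

    def resolve_samples(self, n_edges: int) -> int:
        if self.samples is not None:
            return self.samples
        return max(100 * n_edges, 1_000_000)


@dataclass
class EmbeddingModel:
    """Trained node vectors; only ``u`` is exported as features."""

    dim: int
    nodes: np.ndarray  # global bin indices, aligned with rows of u
    u: np.ndarray
    u_ctx: np.ndarray
    trained: bool = False
    seed: int = 0


def init_model(graph: ContactGraph, config: TrainConfig) -> EmbeddingModel:
    """Uniform(-0.5/dim, 0.5/dim) node vectors, zero context vectors."""
    rng = np.random.default_rng(config.seed)
    u = rng.uniform(-0.5 / config.dim, 0.5 / config.dim, (graph.n_nodes, config.dim))
    ctx = np.zeros((graph.n_nodes, config.dim))
    return EmbeddingModel(config.dim, graph.nodes.copy(), u, ctx, False, config.seed)


# ---------------------------------------------------------------------------
# exact quantities (oracle / diagnostic use on small graphs)


def _logits(model: EmbeddingModel) -> np.ndarray:
    return model.u @ model.u_ctx.T  # [i, j] = u'_j . u_i


def second_order_softmax(model: EmbeddingModel, i: int) -> np.ndarray:
    """p2(. | i): probability over all nodes, overflow-guarded."""
    logit = model.u_ctx @ model.u[i]
    logit -= logit.max()
    p = np.exp(logit)
    return p / p.sum()


def empirical_distribution(graph: ContactGraph, i: int) -> np.ndarray:
    """p̂2(. | i) = w_ij / d_i over all nodes (zero off the neighbours)."""
    p = np.zeros(graph.n_nodes)
    for a, b, w in zip(graph.edge_i, graph.edge_j, graph.weight):
        if a == i:
            p[b] += w
        elif b == i:
            p[a] += w
    d = p.sum()
    if d == 0:
        raise ValueError(f"node {i} is isolated; drop isolated nodes before training")
    return p / d


def exact_objective(model: EmbeddingModel, graph: ContactGraph) -> float:
    """Full-softmax objective; each undirected edge contributes both
    directions. Oracle use only (quadratic in |V|)."""
    logits = _logits(model)
    lse = logsumexp(logits, axis=1)
    i, j, w = graph.edge_i, graph.edge_j, graph.weight
    return float(
        -np.sum(w * (logits[i, j] - lse[i])) - np.sum(w * (logits[j, i] - lse[j]))
    )


def exact_gradient(model: EmbeddingModel, graph: ContactGraph):
    """Analytic gradient of :func:`exact_objective` w.r.t. (u, u_ctx)."""
    n = graph.n_nodes
    A = np.zeros((n, n))
    A[graph.edge_i, graph.edge_j] = graph.weight
    A = A + A.T
    d = A.sum(axis=1)
    logits = _logits(model)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    grad_u = -A @ model.u_ctx + d[:, None] * (P @ model.u_ctx)
    grad_ctx = -A @ model.u + P.T @ (d[:, None] * model.u)
    return grad_u, grad_ctx


def first_order_objective(model: EmbeddingModel, graph: ContactGraph) -> float:
    """-sum_E w log sigma(u_i . u_j): diagnostic for comparing first-
    vs second-order embeddings on synthetic graphs."""
    dots = np.einsum(
        "ed,ed->e", model.u[graph.edge_i], model.u[graph.edge_j]
    )
    return float(np.sum(graph.weight * np.logaddexp(0.0, -dots)))


# ---------------------------------------------------------------------------
# alias tables (Vose's method)


def build_alias(weights: np.ndarray):
    """O(1) discrete sampling table for probabilities ∝ weights."""
    n = weights.size
    p = weights / weights.sum() * n
    prob = np.zeros(n)
    alias = np.zeros(n, dtype=np.int64)
    small = [k for k in range(n) if p[k] < 1.0]
    large = [k for k in range(n) if p[k] >= 1.0]
    p = p.copy()
    while small and large:
        s = small.pop()
        l = large.pop()
        prob[s] = p[s]
        alias[s] = l
        p[l] = p[l] - (1.0 - p[s])
        (small if p[l] < 1.0 else large).append(l)
    for k in large:
        prob[k] = 1.0
    for k in small:
        prob[k] = 1.0
    return prob, alias


# ---------------------------------------------------------------------------
# SGD trainer


@njit(cache=False)
def _sigmoid(x):
    if x > 35.0:
        return 1.0
    if x < -35.0:
        return 0.0
    return 1.0 / (1.0 + np.exp(-x))


@njit(cache=False)
def _sgd(
    src,
    dst,
    edge_prob,
    edge_alias,
    noise_prob,
    noise_alias,
    u,
    ctx,
    T,
    K_neg,
    rho0,
    rho_min,
    seed,
):
    np.random.seed(seed)
    n_edges = src.shape[0]
    n_nodes = u.shape[0]
    dim = u.shape[1]
    buf = np.empty(dim)
    for t in range(T):
        rho = rho0 * (1.0 - t / T)
        if rho < rho_min:
            rho = rho_min
        k = int(np.random.random() * n_edges)
        e = k if np.random.random() < edge_prob[k] else edge_alias[k]
        a = src[e]
        b = dst[e]
        for direction in range(2):
            if direction == 0:
                i, j = a, b
            else:
                i, j = b, a
            for d in range(dim):
                buf[d] = 0.0
            # positive pair: ascend log sigma(u'_j . u_i)
            dot = 0.0
            for d in range(dim):
                dot += ctx[j, d] * u[i, d]
            g = rho * (1.0 - _sigmoid(dot))
            for d in range(dim):
                buf[d] += g * ctx[j, d]
                ctx[j, d] += g * u[i, d]
            # negatives: descend log sigma(u'_m . u_i)
            for _ in range(K_neg):
                kk = int(np.random.random() * n_nodes)
                m = kk if np.random.random() < noise_prob[kk] else noise_alias[kk]
                if m == j:
                    continue
                dot = 0.0
                for d in range(dim):
                    dot += ctx[m, d] * u[i, d]
                g = -rho * _sigmoid(dot)
                for d in range(dim):
                    buf[d] += g * ctx[m, d]
                    ctx[m, d] += g * u[i, d]
            for d in range(dim):
                u[i, d] += buf[d]


def train(graph: ContactGraph, config: TrainConfig | None = None) -> EmbeddingModel:
    """Train node embeddings by weighted edge sampling with negative
    sampling. Deterministic for a fixed seed (single threaded)."""
    if config is None:
        config = TrainConfig()
    if graph.n_edges == 0:
        raise ValueError("cannot embed an empty graph")
    deg = graph.degree
    if np.any(deg <= 0):
        raise ValueError("graph contains isolated nodes; drop them before training")
    T = config.resolve_samples(graph.n_edges)
    model = init_model(graph, config)
    edge_prob, edge_alias = build_alias(graph.weight)
    noise_prob, noise_alias = build_alias(deg**config.noise_exponent)
    _sgd(
        graph.edge_i.astype(np.int64),
        graph.edge_j.astype(np.int64),
        edge_prob,
        edge_alias,
        noise_prob,
        noise_alias,
        model.u,
        model.u_ctx,
        T,
        config.negatives,
        config.rho0,
        config.rho0 * config.rho_min_frac,
        # numba's legacy RNG seed must stay in uint32 range
        int(config.seed) % (2**32 - 1),
    )
    model.trained = True
    return model


def export_features(
    model: EmbeddingModel, genome: BinnedGenome, mask: np.ndarray | None = None
) -> FeatureMatrix:
    """Place node vectors at their global bin rows; bins outside the
    graph (or masked) get zero rows with mask False."""
    values = np.zeros((genome.n_bins, model.dim))
    out_mask = np.zeros(genome.n_bins, dtype=bool)
    values[model.nodes] = model.u
    out_mask[model.nodes] = True
    if mask is not None:
        out_mask &= np.asarray(mask, dtype=bool)
    names = [f"struct_{k + 1}" for k in range(model.dim)]
    return FeatureMatrix(values, names, out_mask)
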