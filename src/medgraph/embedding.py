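"""Node embeddings via p/q-biased random walks and skip-gram negative sampling.

The sampler performs second-order (node2vec-style) walks: from the current
node, the unnormalized probability of stepping to a neighbor is 1/p if it
returns to the previous node, 1 if it stays at graph distance 1 from the
previous node, and 1/q if it moves to distance 2. Small q biases the walk
outward (depth-first-like); large q keeps it local (breadth-first-like).

The walk corpus is then fed to a skip-gram model with negative sampling:
for each (center, context) pair within the window the objective

    J = log sigma(u_o . v_c) + sum_j log sigma(-u_j . v_c)

is maximized by stochastic gradient ascent, with the j noise nodes drawn from
the unigram distribution raised to ``noise_exponent``. Edge labels are
ignored during walking: the embedding encodes graph structure only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "EmbeddingConfig",
    "WalkCorpus",
    "SkipGramParams",
    "EmbeddingMatrix",
    "transition_distribution",
    "sample_walks",
    "negative_sampling_loss",
    "negative_sampling_gradients",
    "train_skipgram",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Hyperparameters of the walk sampler and skip-gram trainer.

    Defaults are the tuned values of the reference configuration: 128
    dimensions, context window 5, 7 negatives, return bias p=2, in-out bias
    q=0.5, walks of 50 nodes, 5 walks per node.
    """

    dim: int = 128
    window: int = 5
    negatives: int = 7
    p: float = 2.0
    q: float = 0.5
    walk_length: int = 50
    walks_per_node: int = 5
    epochs: int = 5
    noise_exponent: float = 0.75
    alpha: float = 0.025       # initial learning rate, linearly decayed
    min_alpha: float = 1e-4    # learning-rate floor
    seed: int = 0

    def validate(self) -> None:
        if self.dim < 1 or self.window < 1 or self.walk_length < 1 \
                or self.walks_per_node < 1 or self.epochs < 1:
            raise ValueError("dim, window, walk_length, walks_per_node, epochs must be >= 1")
        if self.negatives < 0:
            raise ValueError("negatives must be >= 0")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


@dataclass
class WalkCorpus:
    walks: list[list[str]]

    @property
    def total_tokens(self) -> int:
        return sum(len(w) for w in self.walks)


@dataclass
class SkipGramParams:
    """Input (v) and output (u) vector tables over a shared vocabulary."""

    vocab: list[str]
    input_vectors: np.ndarray   # (|vocab|, d) — the released embeddings
    output_vectors: np.ndarray  # (|vocab|, d)


class EmbeddingMatrix:
    """Node-id -> d-vector mapping with word2vec-text persistence."""

    def __init__(self, vocab: list[str], vectors: np.ndarray):
        if len(vocab) != vectors.shape[0]:
            raise ValueError("vocab / vector row count mismatch")
        self.vocab = list(vocab)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self._index = {n: i for i, n in enumerate(self.vocab)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __getitem__(self, node_id: str) -> np.ndarray:
        return self.vectors[self._index[node_id]]

    def __len__(self) -> int:
        return len(self.vocab)

    def items(self):
        for n in self.vocab:
            yield n, self.vectors[self._index[n]]

    def save(self, path: str | Path) -> None:
        """First line ``<vocab> <dim>``, then ``<node-id> <d floats>``."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.vocab)} {self.dim}\n")
            for n, v in self.items():
                fh.write(n + " " + " ".join(f"{x:.8e}" for x in v) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingMatrix":
        with open(path) as fh:
            n, d = map(int, fh.readline().split())
            vocab, rows = [], []
            for line in fh:
                parts = line.rstrip("\n").split(" ")
                vocab.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(vocab) != n or (rows and len(rows[0]) != d):
            raise ValueError("corrupt embedding file")
        return cls(vocab, np.array(rows, dtype=np.float64).reshape(n, d))


# ---------------------------------------------------------------------------
# biased walks

def _adjacency(graph: nx.Graph) -> tuple[list[str], dict[str, list[str]], dict[str, set[str]]]:
    nodes = sorted(graph.nodes)
    nbrs = {n: sorted(set(graph.neighbors(n)) - {n}) for n in nodes}
    nbr_sets = {n: set(v) for n, v in nbrs.items()}
    return nodes, nbrs, nbr_sets


def _transition_weights(nbrs_of_cur: list[str], prev_set: set[str], prev: str,
                        p: float, q: float) -> np.ndarray:
    w = np.empty(len(nbrs_of_cur))
    for i, nb in enumerate(nbrs_of_cur):
        if nb == prev:
            w[i] = 1.0 / p
        elif nb in prev_set:
            w[i] = 1.0
        else:
            w[i] = 1.0 / q
    return w


def transition_distribution(graph: nx.Graph, prev: str | None, cur: str,
                            p: float, q: float) -> dict[str, float]:
    """Normalized second-order transition probabilities out of ``cur``.

    With no previous node (first step) the distribution is uniform over the
    neighbors of ``cur``. A node with no neighbors yields an empty map.
    """
    nbrs = sorted(set(graph.neighbors(cur)) - {cur})
    if not nbrs:
        return {}
    if prev is None:
        return {nb: 1.0 / len(nbrs) for nb in nbrs}
    prev_set = set(graph.neighbors(prev))
    w = _transition_weights(nbrs, prev_set, prev, p, q)
    w /= w.sum()
    return dict(zip(nbrs, w))


def sample_walks(graph: nx.Graph, config: EmbeddingConfig) -> WalkCorpus:
    """``walks_per_node`` biased walks from every node, each at most
    ``walk_length`` nodes; walks truncate at dead ends. Deterministic for a
    fixed seed (nodes visited in sorted order)."""
    config.validate()
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA1C]))
    nodes, nbrs, nbr_sets = _adjacency(graph)
    walks: list[list[str]] = []
    for _ in range(config.walks_per_node):
        for start in nodes:
            walk = [start]
            prev: str | None = None
            while len(walk) < config.walk_length:
                cur = walk[-1]
                cur_nbrs = nbrs[cur]
                if not cur_nbrs:
                    break
                if prev is None:
                    nxt = cur_nbrs[int(rng.integers(len(cur_nbrs)))]
                else:
                    w = _transition_weights(cur_nbrs, nbr_sets[prev], prev,
                                            config.p, config.q)
                    cum = np.cumsum(w)
                    nxt = cur_nbrs[int(np.searchsorted(cum, rng.random() * cum[-1],
                                                       side="right"))]
                prev = cur
                walk.append(nxt)
            walks.append(walk)
    return WalkCorpus(walks=walks)


# ---------------------------------------------------------------------------
# skip-gram with negative sampling

_MAX_EXP = 12.0  # logits are clipped here; sigma saturates far earlier


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_MAX_EXP, _MAX_EXP)))


def negative_sampling_loss(center: str, context: str, negatives: list[str],
                           params: SkipGramParams) -> float:
    """log sigma(u_o . v_c) + sum_j log sigma(-u_j . v_c); maximized during
    training (0 is the supremum)."""
    idx = {n: i for i, n in enumerate(params.vocab)}
    v_c = params.input_vectors[idx[center]]
    u_o = params.output_vectors[idx[context]]
    loss = float(np.log(_sigmoid(u_o @ v_c)))
    for neg in negatives:
        u_j = params.output_vectors[idx[neg]]
        loss += float(np.log(_sigmoid(-(u_j @ v_c))))
    return loss


def negative_sampling_gradients(v_c: np.ndarray, u_o: np.ndarray,
                                U_neg: np.ndarray):
    """Analytic gradients of the pairwise objective with respect to
    (v_c, u_o, each u_j). Returns (loss, g_v, g_uo, G_neg)."""
    pos = float(_sigmoid(u_o @ v_c))
    negs = _sigmoid(U_neg @ v_c) if len(U_neg) else np.empty(0)
    loss = math.log(pos) + float(np.sum(np.log(1.0 - negs))) if len(U_neg) \
        else math.log(pos)
    g_v = (1.0 - pos) * u_o - (negs[:, None] * U_neg).sum(axis=0) if len(U_neg) \
        else (1.0 - pos) * u_o
    g_uo = (1.0 - pos) * v_c
    G_neg = -negs[:, None] * v_c if len(U_neg) else np.empty((0, len(v_c)))
    return loss, g_v, g_uo, G_neg


def _sgd_kernel(W_in, W_out, centers, contexts, negatives, alphas):
    # sequential SGD over (center, context) pairs; mutates W_in / W_out
    n_pairs = centers.shape[0]
    k = negatives.shape[1]
    d = W_in.shape[1]
    for i in range(n_pairs):
        c = centers[i]
        o = contexts[i]
        lr = alphas[i]
        grad_v = np.zeros(d)
        s = 0.0
        for j in range(d):
            s += W_in[c, j] * W_out[o, j]
        if s > 12.0:
            s = 12.0
        elif s < -12.0:
            s = -12.0
        g = (1.0 - 1.0 / (1.0 + math.exp(-s))) * lr
        for j in range(d):
            grad_v[j] += g * W_out[o, j]
            W_out[o, j] += g * W_in[c, j]
        for t in range(k):
            u = negatives[i, t]
            if u == o:
                continue
            s = 0.0
            for j in range(d):
                s += W_in[c, j] * W_out[u, j]
            if s > 12.0:
                s = 12.0
            elif s < -12.0:
                s = -12.0
            g = -(1.0 / (1.0 + math.exp(-s))) * lr
            for j in range(d):
                grad_v[j] += g * W_out[u, j]
                W_out[u, j] += g * W_in[c, j]
        for j in range(d):
            W_in[c, j] += grad_v[j]


try:  # compiled fast path; the pure-Python kernel is the reference semantics
    from numba import njit as _njit

    _sgd_step = _njit(cache=True)(_sgd_kernel)
except ImportError:  # pragma: no cover
    _sgd_step = _sgd_kernel


def _corpus_pairs(walks_idx: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for w in walks_idx:
        L = len(w)
        for t in range(L):
            lo = max(0, t - window)
            hi = min(L, t + window + 1)
            for j in range(lo, hi):
                if j != t:
                    centers.append(w[t])
                    contexts.append(w[j])
    return (np.array(centers, dtype=np.int64),
            np.array(contexts, dtype=np.int64))


def train_skipgram(corpus: WalkCorpus, config: EmbeddingConfig) -> EmbeddingMatrix:
    """Train skip-gram with negative sampling on a walk corpus.

    One positive pair per (position, offset) with |offset| <= window, plus
    ``negatives`` noise nodes per pair drawn from the unigram distribution
    raised to ``noise_exponent``. The learning rate decays linearly from
    ``alpha`` to ``min_alpha`` over all updates. Single-threaded and
    deterministic given the seed; returns the input vectors.
    """
    config.validate()
    if not corpus.walks or corpus.total_tokens == 0:
        raise ValueError("corpus is empty")
    vocab = sorted({n for w in corpus.walks for n in w})
    index = {n: i for i, n in enumerate(vocab)}
    V = len(vocab)
    counts = np.zeros(V)
    walks_idx = []
    for w in corpus.walks:
        iw = np.array([index[n] for n in w], dtype=np.int64)
        walks_idx.append(iw)
        np.add.at(counts, iw, 1)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5C1]))
    W_in = (rng.random((V, config.dim)) - 0.5) / config.dim
    W_out = np.zeros((V, config.dim))

    centers, contexts = _corpus_pairs(walks_idx, config.window)
    n_pairs = len(centers)
    if n_pairs == 0:  # single-node walks only: keep initial vectors
        return EmbeddingMatrix(vocab, W_in)

    noise = counts ** config.noise_exponent
    noise_cum = np.cumsum(noise / noise.sum())

    total = n_pairs * config.epochs
    step0 = 0
    for _ in range(config.epochs):
        steps = step0 + np.arange(n_pairs)
        alphas = config.alpha + (config.min_alpha - config.alpha) * steps / max(total - 1, 1)
        negs = np.searchsorted(
            noise_cum, rng.random((n_pairs, max(config.negatives, 1)))
        ).astype(np.int64)
        if config.negatives == 0:
            negs = np.empty((n_pairs, 0), dtype=np.int64)
        _sgd_step(W_in, W_out, centers, contexts, negs, alphas)
        step0 += n_pairs
    return EmbeddingMatrix(vocab, W_in)


def embed_graph(graph: nx.Graph, config: EmbeddingConfig) -> EmbeddingMatrix:
    """Convenience: sample walks then train; every KG node receives a vector
    (walks start from each node, so the vocabulary covers the graph)."""
    return train_skipgram(sample_walks(graph, config), config)
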