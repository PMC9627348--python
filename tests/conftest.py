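import numpy as np
import pytest

from medgraph import SynthConfig, generate_tables


@pytest.fixture(scope="session")
def small_tables():
    return generate_tables(SynthConfig(n_articles=50, seed=3))


# ---------------------------------------------------------------------------
# independent oracles used across test modules


def dp_levenshtein(a: str, b: str) -> int:
    """Full dynamic-programming edit-distance matrix."""
    m, n = len(a), len(b)
    D = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        D[i][0] = i
    for j in range(n + 1):
        D[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1,
                          D[i - 1][j - 1] + cost)
    return D[m][n]


def brute_transition(graph, prev, cur, p, q):
    """Independent enumeration of second-order walk weights."""
    nbrs = sorted(set(graph.neighbors(cur)) - {cur})
    if not nbrs:
        return {}
    if prev is None:
        return {n: 1.0 / len(nbrs) for n in nbrs}
    weights = {}
    for n in nbrs:
        if n == prev:
            weights[n] = 1.0 / p
        elif graph.has_edge(prev, n):
            weights[n] = 1.0
        else:
            weights[n] = 1.0 / q
    z = sum(weights.values())
    return {n: w / z for n, w in weights.items()}


def brute_metrics(retrieved, relevant, k):
    """Brute-force P/R/F1/AP@K (standard AP), position by position."""
    rel = set(relevant)
    top = list(retrieved)[:k]
    hits = [p in rel for p in top]
    n_hits = sum(hits)
    precision = n_hits / len(top) if top else 0.0
    recall = n_hits / len(rel)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    ap_terms = []
    running = 0
    for i, h in enumerate(hits, start=1):
        if h:
            running += 1
            ap_terms.append(running / i)
    ap = sum(ap_terms) / min(len(rel), k)
    return precision, recall, f1, ap


def random_retrieval_instance(rng):
    universe = np.arange(1, 200)
    n_ret = int(rng.integers(1, 50))
    n_rel = int(rng.integers(1, 40))
    retrieved = list(rng.choice(universe, size=n_ret, replace=False))
    relevant = set(rng.choice(universe, size=n_rel, replace=False).tolist())
    k = int(rng.integers(1, 60))
    return retrieved, relevant, k
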