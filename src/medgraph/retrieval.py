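"""Article and query vectors, cosine ranking, and the end-to-end search.

Article vectors are built in two pooling stages over the knowledge graph:

* stage 1 — every article node is represented by the mean of the raw
  embedding vectors of ALL its first-order neighbors (authors, entities,
  projects, MeSH terms, cited articles alike);
* stage 2 — each searchable target article is represented by the mean of the
  stage-1 vectors of its first-order ARTICLE (citation) neighbors; an uncited
  target falls back to its own stage-1 vector.

Query vectors are the mean of the matched entities' raw node vectors, and
articles are ranked by cosine similarity to the query vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .embedding import EmbeddingMatrix
from .kg import EntityIndex, node_type
from .query import ExpandedQuery, MatchSet, NoMatchError, TokenizedQuery, expand, match, tokenize

__all__ = [
    "ArticleVectors",
    "RankedResult",
    "SystemState",
    "pool_neighbors",
    "article_embeddings",
    "embed_query",
    "cosine",
    "rank",
    "search",
]

log = logging.getLogger("medgraph.retrieval")


@dataclass
class ArticleVectors:
    """pmid-prefixed node-id -> d-vector, tagged with the pooling stage."""

    vectors: dict[str, np.ndarray]
    stage: str  # "stage1" | "stage2"
    targets: set[str] = field(default_factory=set)

    @property
    def dim(self) -> int:
        v = next(iter(self.vectors.values()))
        return len(v)

    def save(self, path) -> None:
        m = EmbeddingMatrix(sorted(self.vectors),
                            np.array([self.vectors[k] for k in sorted(self.vectors)]))
        m.save(path)

    @classmethod
    def load(cls, path, stage: str = "stage2") -> "ArticleVectors":
        m = EmbeddingMatrix.load(path)
        vecs = {n: v.copy() for n, v in m.items()}
        return cls(vectors=vecs, stage=stage, targets=set(vecs))


@dataclass
class RankedResult:
    query_id: str
    items: list[tuple[int, float]]  # (pmid, cosine score), non-increasing
    k: int

    @property
    def pmids(self) -> list[int]:
        return [p for p, _ in self.items]


def pool_neighbors(graph: nx.Graph, vectors, node: str,
                   neighbor_types: set[str] | None = None,
                   include_self: bool = False) -> np.ndarray:
    """Arithmetic mean of the selected first-order neighbors' vectors.

    ``vectors`` is any mapping node-id -> vector (an EmbeddingMatrix or a
    plain dict). ``neighbor_types`` filters by node type; None keeps all.
    """
    if node not in graph:
        raise KeyError(f"node not in graph: {node!r}")
    selected = []
    for nb in set(graph.neighbors(node)) - {node}:
        if neighbor_types is not None and node_type(nb) not in neighbor_types:
            continue
        if nb in vectors:
            selected.append(np.asarray(vectors[nb], dtype=np.float64))
    if include_self and node in vectors:
        selected.append(np.asarray(vectors[node], dtype=np.float64))
    if not selected:
        raise ValueError(f"no vectors selected for node {node!r}")
    return np.mean(selected, axis=0)


def article_embeddings(graph: nx.Graph, emb: EmbeddingMatrix,
                       targets: set[str]) -> ArticleVectors:
    """Two-stage pooled article vectors for the given target article nodes."""
    articles = [n for n, t in graph.nodes(data="node_type") if t == "article"]
    missing = sorted(t for t in targets if t not in graph)
    if missing:
        raise KeyError(f"target articles absent from graph: {missing}")
    stage1: dict[str, np.ndarray] = {}
    for a in articles:
        try:
            stage1[a] = pool_neighbors(graph, emb, a)
        except ValueError:
            # isolated article: fall back to its own raw vector
            stage1[a] = np.asarray(emb[a], dtype=np.float64)
    stage2: dict[str, np.ndarray] = {}
    for a in sorted(targets):
        try:
            stage2[a] = pool_neighbors(graph, stage1, a, neighbor_types={"article"})
        except ValueError:
            stage2[a] = stage1[a]  # uncited target: stage-1 fallback
    return ArticleVectors(vectors=stage2, stage="stage2", targets=set(targets))


def embed_query(match_set: MatchSet, emb: EmbeddingMatrix,
                index: EntityIndex) -> np.ndarray:
    """Mean of the matched entities' node vectors."""
    if not match_set.matched:
        raise NoMatchError("query matched no indexed entity")
    vecs = []
    for _, eid, _ in match_set.matched:
        nid = index.node_id(eid)
        if nid not in emb:
            raise KeyError(f"matched entity has no embedding: {nid}")
        vecs.append(emb[nid])
    return np.mean(vecs, axis=0)


def cosine(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine undefined for zero vector")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def _pmid_of(node_id: str) -> int:
    return int(node_id.rsplit("/", 1)[1])


def rank(query_vec: np.ndarray, av: ArticleVectors, k: int,
         query_id: str = "") -> RankedResult:
    """All target articles scored by cosine, sorted descending; ties break
    toward the ascending pmid; truncated to ``k``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not av.vectors:
        return RankedResult(query_id=query_id, items=[], k=k)
    scored = [(_pmid_of(n), cosine(query_vec, v)) for n, v in av.vectors.items()]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return RankedResult(query_id=query_id, items=scored[:k], k=k)


@dataclass
class SystemState:
    """Everything the search frontend needs, loaded once."""

    graph: nx.Graph
    index: EntityIndex
    embeddings: EmbeddingMatrix
    article_vectors: ArticleVectors
    windows: frozenset[int] = frozenset({2, 3, 4})
    max_distance: int = 1


def search(text: str, state: SystemState, k: int = 10,
           query_id: str = "") -> RankedResult:
    """tokenize -> expand -> match -> embed -> rank.

    Raises :class:`~medgraph.query.NoMatchError` when no keyword matches any
    indexed entity — the clean "no results" outcome, distinct from internal
    failures.
    """
    tq = tokenize(text)
    eq = expand(tq, windows=state.windows)
    ms = match(eq, state.index, max_distance=state.max_distance)
    log.info("query=%r tokens=%d keywords=%d matched=%d",
             text, len(tq.tokens), len(eq.keywords), len(ms.matched))
    if not ms.matched:
        raise NoMatchError(f"no results for query: {text!r}")
    qv = embed_query(ms, state.embeddings, state.index)
    return rank(qv, state.article_vectors, k, query_id=query_id)
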