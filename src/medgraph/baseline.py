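"""TF-IDF bag-of-words ranking baseline.

Documents (title + abstract token streams) are weighted by raw term frequency
times idf = log(N / df) and L2-normalized; queries are vectorized with the
fitted idf and ranked by cosine similarity, with the same pmid tie rule as
the graph-based ranker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .retrieval import RankedResult

__all__ = ["TfidfModel", "fit_tfidf", "tfidf_rank", "tokenize_document"]


def tokenize_document(text: str) -> list[str]:
    return text.casefold().split()


@dataclass
class TfidfModel:
    vocabulary: dict[str, int]           # term -> column
    idf: np.ndarray                      # (|vocab|,)
    matrix: sp.csr_matrix                # (n_docs, |vocab|), rows L2-normalized
    pmids: list[int]                     # row -> pmid


def fit_tfidf(corpus: dict[int, list[str]]) -> TfidfModel:
    """Fit on a pmid -> token-list corpus.

    tf is the raw within-document count, idf = log(N / df) without smoothing
    (terms present in every document carry zero weight), and document rows
    are L2-normalized. Empty documents yield zero rows.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    pmids = sorted(corpus)
    vocab = sorted({t for toks in corpus.values() for t in toks})
    vocabulary = {t: i for i, t in enumerate(vocab)}
    n_docs = len(pmids)

    rows, cols, vals = [], [], []
    df = np.zeros(len(vocab))
    for r, pmid in enumerate(pmids):
        counts: dict[int, int] = {}
        for t in corpus[pmid]:
            counts[vocabulary[t]] = counts.get(vocabulary[t], 0) + 1
        for c, v in counts.items():
            rows.append(r)
            cols.append(c)
            vals.append(float(v))
            df[c] += 1
    idf = np.log(n_docs / np.where(df > 0, df, 1.0))
    tf = sp.csr_matrix((vals, (rows, cols)), shape=(n_docs, len(vocab)))
    weighted = tf.multiply(idf).tocsr()
    norms = np.sqrt(np.asarray(weighted.multiply(weighted).sum(axis=1)).ravel())
    inv = np.where(norms > 0, 1.0 / np.where(norms > 0, norms, 1.0), 0.0)
    weighted = sp.diags(inv) @ weighted
    return TfidfModel(vocabulary=vocabulary, idf=idf, matrix=weighted.tocsr(),
                      pmids=pmids)


def tfidf_rank(query_tokens: list[str], model: TfidfModel, k: int,
               query_id: str = "") -> RankedResult:
    """Cosine-rank all documents against the tf-idf-weighted query vector.

    A query entirely out of vocabulary (or with only zero-idf terms) returns
    an empty result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    q = np.zeros(len(model.vocabulary))
    for t in query_tokens:
        c = model.vocabulary.get(t)
        if c is not None:
            q[c] += 1.0
    q *= model.idf
    qn = np.linalg.norm(q)
    if qn == 0.0:
        return RankedResult(query_id=query_id, items=[], k=k)
    scores = model.matrix @ (q / qn)
    scored = sorted(zip(model.pmids, scores.tolist()), key=lambda t: (-t[1], t[0]))
    return RankedResult(query_id=query_id, items=scored[:k], k=k)
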