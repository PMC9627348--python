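"""Ranked-retrieval evaluation: precision/recall/F1@K, average precision,
MAP, ground-truth pruning, and the benchmark harness that compares rankers
over a K grid.

Standard definitions are used: precision@K = |relevant ∩ top-K| / K',
recall@K = |relevant ∩ top-K| / |relevant| (K' being the number actually
retrieved). Average precision ships in two variants: the standard one (mean
of precision at the relevant retrieved positions, normalized by
min(|relevant|, K)) and an "all-positions" variant averaging precision over
every retrieved position up to K.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "QueryJudgment",
    "EvalReport",
    "DEFAULT_K_GRID",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "prune_judgments",
    "run_benchmark",
    "read_judgments",
    "write_judgments",
]

DEFAULT_K_GRID = (1, 2, 5, 10, 25, 50, 75, 100, 150, 250, 500, 1000)


@dataclass
class QueryJudgment:
    query_id: str
    query_text: str
    relevant: list[int]  # ground-truth order preserved, duplicate-free

    def __post_init__(self) -> None:
        if not self.relevant:
            raise ValueError(f"judgment for {self.query_id!r} has no relevant documents")
        if len(set(self.relevant)) != len(self.relevant):
            raise ValueError(f"judgment for {self.query_id!r} contains duplicates")


def precision_recall_f1(retrieved: Sequence[int], relevant: Iterable[int],
                        k: int) -> tuple[float, float, float]:
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = set(relevant)
    if not rel:
        raise ValueError("relevant set is empty")
    top = list(retrieved)[:k]
    hits = sum(1 for p in top if p in rel)
    precision = hits / len(top) if top else 0.0
    recall = hits / len(rel)
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def average_precision(retrieved: Sequence[int], relevant: Iterable[int],
                      k: int, variant: str = "standard") -> float:
    """AP@K.

    standard: mean of precision@i over relevant retrieved positions i,
    divided by min(|relevant|, K). all_positions: mean of precision@i over
    all retrieved positions i <= K.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rel = set(relevant)
    if not rel:
        raise ValueError("relevant set is empty")
    top = list(retrieved)[:k]
    hits = 0
    precisions_at_rel = []
    precisions_all = []
    for i, p in enumerate(top, start=1):
        if p in rel:
            hits += 1
            precisions_at_rel.append(hits / i)
        precisions_all.append(hits / i)
    if variant == "standard":
        denom = min(len(rel), k)
        return sum(precisions_at_rel) / denom if denom else 0.0
    if variant == "all_positions":
        return sum(precisions_all) / len(precisions_all) if precisions_all else 0.0
    raise ValueError(f"unknown AP variant: {variant!r}")


def mean_average_precision(results: Mapping[str, Sequence[int]],
                           judgments: Mapping[str, QueryJudgment],
                           k: int, variant: str = "standard") -> float:
    missing = sorted(set(results) - set(judgments))
    if missing:
        raise KeyError(f"queries without judgments: {missing}")
    if not results:
        raise ValueError("no results to evaluate")
    aps = [average_precision(retrieved, judgments[q].relevant, k, variant)
           for q, retrieved in results.items()]
    return sum(aps) / len(aps)


def prune_judgments(judgments: Mapping[str, QueryJudgment],
                    k: int) -> dict[str, QueryJudgment]:
    """Truncate each relevant list to its first K entries (ground-truth
    order), emulating evaluation against only the top of the reference
    ranking."""
    return {
        q: QueryJudgment(j.query_id, j.query_text, j.relevant[:k])
        for q, j in judgments.items()
    }


@dataclass
class EvalReport:
    """Per-(method, K) metric table plus a per-query breakdown."""

    table: pd.DataFrame       # columns: method, k, precision, recall, f1, map
    per_query: pd.DataFrame   # columns: method, k, query_id, precision, recall, f1, ap
    failures: list[tuple[str, str, str]] = field(default_factory=list)  # (method, query, error)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def to_json(self) -> str:
        recs = self.table.round(6).to_dict(orient="records")
        return json.dumps(recs, sort_keys=True)

    def pivot(self, metric: str) -> pd.DataFrame:
        """metric x method x K layout, one row per method."""
        return self.table.pivot(index="method", columns="k", values=metric)


def run_benchmark(methods: Mapping[str, Callable[[str, int], Sequence[int]]],
                  queries: Sequence[tuple[str, str]],
                  judgments: Mapping[str, QueryJudgment],
                  k_grid: Sequence[int] = DEFAULT_K_GRID,
                  prune: bool = False,
                  ap_variant: str = "standard") -> EvalReport:
    """Evaluate named rankers over queries and a K grid.

    Each method is called as ``method(query_text, k)`` and returns an ordered
    pmid list. A failing ranker scores 0 on that query and the run continues.
    With ``prune`` on, the ground truth itself is truncated to its top K at
    every level before scoring.
    """
    if any(k < 1 for k in k_grid):
        raise ValueError("k grid entries must be >= 1")
    missing = [qid for qid, _ in queries if qid not in judgments]
    if missing:
        raise KeyError(f"queries without judgments: {missing}")

    k_max = max(k_grid)
    retrieved: dict[tuple[str, str], list[int]] = {}
    failures: list[tuple[str, str, str]] = []
    for mname, fn in methods.items():
        for qid, qtext in queries:
            try:
                retrieved[(mname, qid)] = list(fn(qtext, k_max))
            except Exception as e:  # ranker failure -> scored 0, run continues
                retrieved[(mname, qid)] = []
                failures.append((mname, qid, str(e)))

    rows, q_rows = [], []
    for k in k_grid:
        judged = prune_judgments(judgments, k) if prune else judgments
        for mname in methods:
            ps, rs, fs, aps = [], [], [], []
            for qid, _ in queries:
                rel = judged[qid].relevant
                got = retrieved[(mname, qid)]
                if got:
                    p, r, f1 = precision_recall_f1(got, rel, k)
                    ap = average_precision(got, rel, k, ap_variant)
                else:
                    p = r = f1 = ap = 0.0
                ps.append(p)
                rs.append(r)
                fs.append(f1)
                aps.append(ap)
                q_rows.append((mname, k, qid, p, r, f1, ap))
            n = len(queries)
            rows.append((mname, k, sum(ps) / n, sum(rs) / n, sum(fs) / n,
                         sum(aps) / n))
    table = pd.DataFrame(rows, columns=["method", "k", "precision", "recall",
                                        "f1", "map"])
    per_query = pd.DataFrame(q_rows, columns=["method", "k", "query_id",
                                              "precision", "recall", "f1", "ap"])
    return EvalReport(table=table, per_query=per_query, failures=failures)


def write_judgments(judgments: Mapping[str, QueryJudgment],
                    path: str | Path) -> None:
    """TSV: query-id, query-text, tab-separated relevant pmids in rank order."""
    with open(path, "w") as fh:
        fh.write("query_id\tquery_text\trelevant\n")
        for qid in sorted(judgments):
            j = judgments[qid]
            fh.write(f"{qid}\t{j.query_text}\t" +
                     " ".join(str(p) for p in j.relevant) + "\n")


def read_judgments(path: str | Path) -> dict[str, QueryJudgment]:
    out: dict[str, QueryJudgment] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("query_id"):
            raise ValueError("malformed judgments file")
        for line in fh:
            qid, qtext, rel = line.rstrip("\n").split("\t")
            out[qid] = QueryJudgment(qid, qtext, [int(x) for x in rel.split()])
    return out
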