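"""End-to-end pipeline plumbing: configuration, state persistence, and the
simulate -> build-kg -> embed -> pool -> index -> evaluate chain.

All randomness flows from the single config seed through fixed named
substreams per stage, so one seed reproduces the entire run byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import baseline, evaluation, kg, retrieval, synth
from .embedding import EmbeddingConfig, EmbeddingMatrix, embed_graph
from .evaluation import DEFAULT_K_GRID, EvalReport, QueryJudgment
from .kg import EntityIndex
from .query import NoMatchError
from .retrieval import ArticleVectors, SystemState
from .synth import SynthConfig, SynthTables

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "load_state",
    "save_state",
    "build_state",
    "run_pipeline",
]

log = logging.getLogger("medgraph.pipeline")


class PipelineError(RuntimeError):
    def __init__(self, code: str, message: str):
        super().__init__(message)
        self.code = code


@dataclass
class PipelineConfig:
    """One file configures the whole run; unknown keys are rejected."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    n_queries: int = 15
    k_grid: tuple[int, ...] = DEFAULT_K_GRID
    windows: tuple[int, ...] = (2, 3, 4)
    max_distance: int = 1
    prune: bool = False
    ap_variant: str = "standard"
    seed: int = 0

    def validate(self) -> None:
        self.synth.validate()
        self.embedding.validate()
        if not self.k_grid or any(k < 1 for k in self.k_grid):
            raise PipelineError("config", "k_grid entries must be >= 1")
        if self.n_queries < 1:
            raise PipelineError("config", "n_queries must be >= 1")
        if self.max_distance < 0:
            raise PipelineError("config", "max_distance must be >= 0")
        if self.ap_variant not in ("standard", "all_positions"):
            raise PipelineError("config", f"unknown ap_variant {self.ap_variant!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "synth" in kwargs:
            sk = {f.name for f in dataclasses.fields(SynthConfig)}
            bad = set(kwargs["synth"]) - sk
            if bad:
                raise PipelineError("config", f"unknown synth keys: {sorted(bad)}")
            s = dict(kwargs["synth"])
            for key in ("mentions_per_article", "citations_per_article"):
                if key in s:
                    s[key] = tuple(s[key])
            kwargs["synth"] = SynthConfig(**s)
        if "embedding" in kwargs:
            ek = {f.name for f in dataclasses.fields(EmbeddingConfig)}
            bad = set(kwargs["embedding"]) - ek
            if bad:
                raise PipelineError("config", f"unknown embedding keys: {sorted(bad)}")
            kwargs["embedding"] = EmbeddingConfig(**kwargs["embedding"])
        for key in ("k_grid", "windows"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        # the top-level seed is authoritative: stages derive their streams from it
        cfg = dataclasses.replace(
            cfg,
            synth=dataclasses.replace(cfg.synth, seed=cfg.seed),
            embedding=dataclasses.replace(cfg.embedding, seed=cfg.seed + 1),
        )
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def save_state(state: SystemState, state_dir: str | Path) -> None:
    d = Path(state_dir)
    d.mkdir(parents=True, exist_ok=True)
    kg.write_graph(state.graph, d)
    (d / "index.json").write_text(state.index.to_json() + "\n")
    state.embeddings.save(d / "vectors.w2v")
    state.article_vectors.save(d / "articles.w2v")


def load_state(state_dir: str | Path, windows=frozenset({2, 3, 4}),
               max_distance: int = 1) -> SystemState:
    """Load and cross-validate the four persisted artifacts."""
    d = Path(state_dir)
    for fname in ("kg.nodes.tsv", "kg.edges.tsv", "index.json",
                  "vectors.w2v", "articles.w2v"):
        if not (d / fname).exists():
            raise PipelineError("missing-artifact", f"missing {fname} in {d}")
    graph = kg.read_graph(d)
    index = EntityIndex.from_json((d / "index.json").read_text())
    emb = EmbeddingMatrix.load(d / "vectors.w2v")
    av = ArticleVectors.load(d / "articles.w2v")
    if av.vectors and av.dim != emb.dim:
        raise PipelineError(
            "dimension-mismatch",
            f"node vectors have dim {emb.dim}, article vectors {av.dim}")
    stray = [n for n in av.vectors if n not in graph]
    if stray:
        raise PipelineError("vocabulary-mismatch",
                            f"article vectors not in KG: {sorted(stray)[:5]}")
    return SystemState(graph=graph, index=index, embeddings=emb,
                       article_vectors=av, windows=frozenset(windows),
                       max_distance=max_distance)


def _timed(stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    out = fn(*args, **kwargs)
    log.info("stage=%s wall=%.2fs", stage, time.perf_counter() - t0)
    return out


def build_state(tables: SynthTables, config: PipelineConfig) -> SystemState:
    """Tables -> KG -> node embeddings -> pooled article vectors -> index."""
    triples = _timed("triples", kg.build_triples, tables)
    graph = _timed("graph", kg.assemble_graph, triples)
    log.info("stage=graph %s", kg.graph_summary(graph))
    emb = _timed("embed", embed_graph, graph, config.embedding)
    targets = {n for n, t in graph.nodes(data="node_type") if t == "article"}
    av = _timed("pool", retrieval.article_embeddings, graph, emb, targets)
    index = _timed("index", kg.build_index, tables.mentions)
    return SystemState(graph=graph, index=index, embeddings=emb,
                       article_vectors=av, windows=frozenset(config.windows),
                       max_distance=config.max_distance)


def _judgments_from_queries(queries) -> tuple[list[tuple[str, str]],
                                              dict[str, QueryJudgment]]:
    qlist, judgments = [], {}
    for i, (text, relevant) in enumerate(queries, start=1):
        qid = f"q{i:02d}"
        qlist.append((qid, text))
        judgments[qid] = QueryJudgment(qid, text, sorted(relevant))
    return qlist, judgments


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None
                 ) -> tuple[EvalReport, SystemState, SynthTables]:
    """Full deterministic run; returns the benchmark report and the built
    state. With ``out_dir`` set, tables, state and reports are persisted."""
    config.validate()
    tables = _timed("simulate", synth.generate_tables, config.synth)
    state = build_state(tables, config)

    queries = synth.generate_query_set(tables, config.n_queries,
                                       seed=config.seed + 2)
    qlist, judgments = _judgments_from_queries(queries)

    corpus = {
        int(r.pmid): baseline.tokenize_document(f"{r.title} {r.abstract}")
        for r in tables.articles.itertuples(index=False)
    }
    tfidf = _timed("tfidf", baseline.fit_tfidf, corpus)

    def medgraph_ranker(text: str, k: int):
        try:
            return retrieval.search(text, state, k=k).pmids
        except NoMatchError:
            return []

    def tfidf_ranker(text: str, k: int):
        return baseline.tfidf_rank(text.casefold().split(), tfidf, k).pmids

    report = _timed(
        "evaluate", evaluation.run_benchmark,
        {"MedGraph": medgraph_ranker, "TFIDF": tfidf_ranker},
        qlist, judgments, k_grid=config.k_grid, prune=config.prune,
        ap_variant=config.ap_variant)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        synth.write_tables(tables, out / "tables")
        save_state(state, out / "state")
        evaluation.write_judgments(judgments, out / "judgments.tsv")
        report.to_tsv(out / "report.tsv")
        (out / "report.json").write_text(report.to_json() + "\n")
        (out / "summary.json").write_text(
            json.dumps(kg.graph_summary(state.graph), indent=2, sort_keys=True) + "\n")
    return report, state, tables
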