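"""Typed knowledge-graph construction from relational metadata tables.

Each metadata row becomes a subject-predicate-object triple; triples are
assembled into an undirected multigraph whose nodes carry one of nine types
(article, author, the four bio-entity types, NIH project, MeSH term, chemical
substance) and whose edges carry one of nine relationship labels. Node
identity is the original identifier concatenated to its type namespace with
slashes, e.g. ``article/pmid/652148``.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import networkx as nx
import pandas as pd

__all__ = [
    "Triple",
    "EntityIndex",
    "RowError",
    "NODE_TYPES",
    "EDGE_LABELS",
    "ENTITY_TYPES",
    "make_node_id",
    "node_type",
    "build_triples",
    "assemble_graph",
    "graph_summary",
    "citation_closure",
    "build_index",
    "normalize_mention",
    "write_graph",
    "read_graph",
]

ENTITY_TYPES = ("drug", "disease", "gene", "species")

# node type -> (prefix segment, id namespace segment)
NODE_TYPES: dict[str, tuple[str, str]] = {
    "article": ("article", "pmid"),
    "author": ("author", "aid"),
    "drug": ("bioentity", "drug"),
    "disease": ("bioentity", "disease"),
    "gene": ("bioentity", "gene"),
    "species": ("bioentity", "species"),
    "nih_project": ("nih_project", "project_id"),
    "mesh_term": ("mesh_term", "header_id"),
    "chemical_substance": ("substance", "substance_id"),
}
_ALIASES = {"nih project": "nih_project", "mesh term": "mesh_term",
            "chemical substance": "chemical_substance"}
_PREFIX_TO_TYPE = {v: k for k, v in NODE_TYPES.items()}

EDGE_LABELS = (
    "article-writtenBy-author",
    "article-mentions-disease",
    "article-mentions-drug",
    "article-mentions-gene",
    "article-mentions-species",
    "article-cites-article",
    "article-isFundedBy-NIHProject",
    "article-relatedTo-MeSHTerm",
    "article-relatedTo-substances",
)


class Triple(NamedTuple):
    head: str
    relation: str
    tail: str


@dataclass
class RowError:
    table: str
    row: int
    reason: str


def make_node_id(node_type: str, raw_id) -> str:
    """Canonical prefixed node identifier, e.g. ``("article", 652148)`` ->
    ``"article/pmid/652148"``. Already-prefixed input is rejected."""
    node_type = _ALIASES.get(node_type, node_type)
    if node_type not in NODE_TYPES:
        raise ValueError(f"unknown node type: {node_type!r}")
    raw = str(raw_id)
    if "/" in raw:
        raise ValueError(f"raw id may not contain '/': {raw!r}")
    prefix, namespace = NODE_TYPES[node_type]
    return f"{prefix}/{namespace}/{raw}"


def node_type(node_id: str) -> str:
    """Node type as a pure function of the id prefix."""
    parts = node_id.split("/")
    if len(parts) != 3:
        raise ValueError(f"malformed node id: {node_id!r}")
    key = (parts[0], parts[1])
    if key not in _PREFIX_TO_TYPE:
        raise ValueError(f"unknown node id prefix: {node_id!r}")
    return _PREFIX_TO_TYPE[key]


# table name -> (head builder, relation, tail builder) applied per row
def _mention_label(etype: str) -> str:
    return f"article-mentions-{etype}"


def build_triples(
    tables, collect_errors: list[RowError] | None = None
) -> list[Triple]:
    """One triple per metadata row (after row-level deduplication).

    ``tables`` is a :class:`~medgraph.synth.SynthTables` or a dict of
    DataFrames with the same keys. Rows with unparseable ids or unknown
    entity types are skipped and reported through ``collect_errors``.
    """
    frames = tables.as_dict() if hasattr(tables, "as_dict") else dict(tables)
    errors = collect_errors if collect_errors is not None else []
    triples: list[Triple] = []
    seen: set[Triple] = set()

    def emit(t: Triple) -> None:
        if t not in seen:
            seen.add(t)
            triples.append(t)

    def rows(name: str) -> Iterable[tuple[int, tuple]]:
        df = frames.get(name)
        if df is None or df.empty:
            return []
        return enumerate(df.itertuples(index=False))

    for i, r in rows("authors"):
        try:
            emit(Triple(make_node_id("article", r.pmid), "isWrittenBy/wrote",
                        make_node_id("author", r.aid)))
        except ValueError as e:
            errors.append(RowError("authors", i, str(e)))
    for i, r in rows("mentions"):
        try:
            if r.entity_type not in ENTITY_TYPES:
                raise ValueError(f"unknown entity type: {r.entity_type!r}")
            emit(Triple(make_node_id(r.entity_type, r.entity_id),
                        "isMentionedIn/mentions",
                        make_node_id("article", r.pmid)))
        except ValueError as e:
            errors.append(RowError("mentions", i, str(e)))
    for i, r in rows("references"):
        try:
            emit(Triple(make_node_id("article", r.pmid), "isCitedBy/cites",
                        make_node_id("article", r.cited_pmid)))
        except ValueError as e:
            errors.append(RowError("references", i, str(e)))
    for i, r in rows("projects"):
        try:
            emit(Triple(make_node_id("article", r.pmid), "isFundedBy/funds",
                        make_node_id("nih_project", r.project_id)))
        except ValueError as e:
            errors.append(RowError("projects", i, str(e)))
    for i, r in rows("mesh"):
        try:
            emit(Triple(make_node_id("article", r.pmid), "isRelatedTo/mesh",
                        make_node_id("mesh_term", r.header_id)))
        except ValueError as e:
            errors.append(RowError("mesh", i, str(e)))
    for i, r in rows("substances"):
        try:
            emit(Triple(make_node_id("article", r.pmid), "isRelatedTo/relates",
                        make_node_id("chemical_substance", r.substance_id)))
        except ValueError as e:
            errors.append(RowError("substances", i, str(e)))
    return triples


_RELATION_TO_LABEL = {
    "isWrittenBy/wrote": "article-writtenBy-author",
    "isCitedBy/cites": "article-cites-article",
    "isFundedBy/funds": "article-isFundedBy-NIHProject",
    "isRelatedTo/mesh": "article-relatedTo-MeSHTerm",
    "isRelatedTo/relates": "article-relatedTo-substances",
}


def _edge_label(triple: Triple) -> str:
    if triple.relation == "isMentionedIn/mentions":
        return _mention_label(node_type(triple.head))
    label = _RELATION_TO_LABEL.get(triple.relation)
    if label is None:
        raise ValueError(f"unknown relation: {triple.relation!r}")
    return label


def assemble_graph(triples: Iterable[Triple]) -> nx.MultiGraph:
    """Undirected multigraph: one labeled edge per distinct unordered
    endpoint pair and label; duplicate triples collapse."""
    g = nx.MultiGraph()
    for t in triples:
        label = _edge_label(t)
        for n in (t.head, t.tail):
            if n not in g:
                g.add_node(n, node_type=node_type(n))
        # MultiGraph keyed by label: re-adding the same (u, v, label) collapses
        g.add_edge(t.head, t.tail, key=label, label=label)
    return g


def graph_summary(g: nx.MultiGraph) -> dict:
    """Per-type node counts and per-label edge counts (the shape of the
    realized-graph description table)."""
    node_counts: dict[str, int] = {}
    for _, t in g.nodes(data="node_type"):
        node_counts[t] = node_counts.get(t, 0) + 1
    edge_counts: dict[str, int] = {}
    for _, _, label in g.edges(keys=True):
        edge_counts[label] = edge_counts.get(label, 0) + 1
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "nodes_by_type": dict(sorted(node_counts.items())),
        "edges_by_label": dict(sorted(edge_counts.items())),
    }


def citation_closure(tables, seed_pmids: set[int], order: int = 1) -> set[int]:
    """First-order citation closure: the seeds plus every article citing or
    cited by a seed in the reference table."""
    if order != 1:
        raise ValueError("only first-order closure is supported")
    if not seed_pmids:
        return set()
    refs = tables.references if hasattr(tables, "references") else tables["references"]
    out = set(seed_pmids)
    for r in refs.itertuples(index=False):
        if r.pmid in seed_pmids:
            out.add(int(r.cited_pmid))
        if r.cited_pmid in seed_pmids:
            out.add(int(r.pmid))
    return out


_PUNCT_RE = re.compile(f"[{re.escape(string.punctuation)}]")
_WS_RE = re.compile(r"\s+")


def normalize_mention(s: str) -> str:
    """Index-key normalization: case-fold, strip punctuation, collapse
    whitespace."""
    return _WS_RE.sub(" ", _PUNCT_RE.sub(" ", s.casefold())).strip()


@dataclass
class EntityIndex:
    """Mapping from normalized mention strings to unique bio-entity ids and
    from entity ids to the articles mentioning them."""

    mention_to_entity: dict[str, int] = field(default_factory=dict)
    entity_type: dict[int, str] = field(default_factory=dict)
    entity_to_articles: dict[int, set[int]] = field(default_factory=dict)

    def node_id(self, entity_id: int) -> str:
        return make_node_id(self.entity_type[entity_id], entity_id)

    def to_json(self) -> str:
        return json.dumps(
            {
                "mention_to_entity": self.mention_to_entity,
                "entity_type": {str(k): v for k, v in self.entity_type.items()},
                "entity_to_articles": {
                    str(k): sorted(v) for k, v in self.entity_to_articles.items()
                },
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EntityIndex":
        d = json.loads(text)
        return cls(
            mention_to_entity={k: int(v) for k, v in d["mention_to_entity"].items()},
            entity_type={int(k): v for k, v in d["entity_type"].items()},
            entity_to_articles={
                int(k): set(v) for k, v in d["entity_to_articles"].items()
            },
        )


def build_index(
    mentions: pd.DataFrame, collect_errors: list[RowError] | None = None
) -> EntityIndex:
    """Build the bio-entity index from the mention table.

    Mention strings are normalized; all surface variants of one entity map to
    its single id. When two entities claim the same normalized surface form,
    the first row encountered wins (deterministic given table order).
    """
    errors = collect_errors if collect_errors is not None else []
    idx = EntityIndex()
    if mentions is None or mentions.empty:
        return idx
    for i, r in enumerate(mentions.itertuples(index=False)):
        if r.entity_type not in ENTITY_TYPES:
            errors.append(RowError("mentions", i, f"unknown entity type: {r.entity_type!r}"))
            continue
        eid = int(r.entity_id)
        key = normalize_mention(str(r.mention))
        if key and key not in idx.mention_to_entity:
            idx.mention_to_entity[key] = eid
        idx.entity_type.setdefault(eid, r.entity_type)
        idx.entity_to_articles.setdefault(eid, set()).add(int(r.pmid))
    return idx


def write_graph(g: nx.MultiGraph, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "kg.nodes.tsv", "w") as fh:
        fh.write("node_id\tnode_type\n")
        for n in sorted(g.nodes):
            fh.write(f"{n}\t{g.nodes[n]['node_type']}\n")
    with open(out / "kg.edges.tsv", "w") as fh:
        fh.write("head\tlabel\ttail\n")
        for u, v, label in sorted(
            (min(u, v), max(u, v), k) for u, v, k in g.edges(keys=True)
        ):
            fh.write(f"{u}\t{label}\t{v}\n")
    with open(out / "kg.summary.json", "w") as fh:
        json.dump(graph_summary(g), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_graph(in_dir: str | Path) -> nx.MultiGraph:
    d = Path(in_dir)
    g = nx.MultiGraph()
    nodes = pd.read_csv(d / "kg.nodes.tsv", sep="\t")
    for r in nodes.itertuples(index=False):
        g.add_node(r.node_id, node_type=r.node_type)
    edges = pd.read_csv(d / "kg.edges.tsv", sep="\t")
    for r in edges.itertuples(index=False):
        g.add_edge(r.head, r.tail, key=r.label, label=r.label)
    return g
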