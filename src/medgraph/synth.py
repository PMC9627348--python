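"""Synthetic PubMed-like metadata tables with planted topical structure.

The generator emulates the relational layout of the PubMed knowledge-graph
metadata export: an article table, an author list, extracted bio-entity
mentions, a citation/reference list, NIH-project links and MeSH assignments,
all joined by PMID. Topical structure is planted so that retrieval quality is
measurable: articles belong to topics, mention entities mostly from their
topic's pool, and cite within-topic with a configurable probability. The
derived ``truth`` table (entity -> articles mentioning it) is the retrieval
ground truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SynthConfig",
    "SynthTables",
    "ConfigError",
    "generate_tables",
    "generate_query_set",
    "write_tables",
    "read_tables",
    "TABLE_FILENAMES",
]

ENTITY_TYPES = ("drug", "disease", "gene", "species")

#: probability that an article draws a mention from its own topic's pool
#: (the remainder is drawn uniformly from all entities)
INTRA_TOPIC_MENTION_PROB = 0.8

#: filler vocabulary prefix — disjoint from every mention string by construction
_FILLER_PREFIX = "lorem"

TABLE_FILENAMES = {
    "articles": "A01_Articles.tsv",
    "authors": "A02_AuthorList.tsv",
    "mentions": "B10_BERN_Main.tsv",
    "references": "C04_ReferenceList.tsv",
    "projects": "C05_NIH_PubMed.tsv",
    "mesh": "mesh.tsv",
    "truth": "truth.tsv",
}


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic corpus.

    Defaults produce the small benchmark corpus used throughout the test
    suite: 200 articles in 4 topics with strongly intra-topic citations.
    """

    n_articles: int = 200
    n_topics: int = 4
    entities_per_topic: int = 5  # per entity type, per topic
    mentions_per_article: tuple[int, int] = (2, 5)
    n_authors: int = 100
    n_projects: int = 20
    n_mesh: int = 30
    citation_intra_topic_prob: float = 0.8
    citations_per_article: tuple[int, int] = (1, 4)
    mention_variant_count: int = 3
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_articles", "n_topics", "entities_per_topic",
                     "n_authors", "mention_variant_count"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_projects", "n_mesh"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("mentions_per_article", "citations_per_article"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ConfigError(f"{name} must be a nondecreasing nonnegative range")
        if self.mentions_per_article[0] < 1:
            raise ConfigError("mentions_per_article lower bound must be >= 1")
        if not 0.0 <= self.citation_intra_topic_prob <= 1.0:
            raise ConfigError("citation_intra_topic_prob must lie in [0, 1]")
        if self.citations_per_article[1] > self.n_articles - 1:
            raise ConfigError(
                "citations_per_article upper bound exceeds n_articles - 1")


@dataclass
class SynthTables:
    """The seven generated tables, as pandas DataFrames."""

    articles: pd.DataFrame    # pmid, title, abstract, topic
    authors: pd.DataFrame     # pmid, aid, name
    mentions: pd.DataFrame    # pmid, entity_id, entity_type, mention
    references: pd.DataFrame  # pmid, cited_pmid
    projects: pd.DataFrame    # pmid, project_id
    mesh: pd.DataFrame        # pmid, header_id
    truth: pd.DataFrame       # entity_id, pmid

    def as_dict(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}


def _entity_base_name(entity_type: str, eid: int) -> str:
    """Deterministic surface form; every 4th entity gets a two-token name."""
    base = f"{entity_type}{eid}"
    if eid % 4 == 0:
        return f"{base} syndrome"
    return base


def _mention_variants(base: str, count: int) -> list[str]:
    """Deterministic surface variants: the base string, a case change, then
    suffixed variants at Levenshtein distance 1 from the base."""
    variants = [base]
    if count > 1:
        variants.append(base.capitalize())
    suffixes = "xyzwv"
    for k in range(count - 2):
        variants.append(base + suffixes[k % len(suffixes)])
    return variants[:count]


def generate_tables(config: SynthConfig) -> SynthTables:
    """Generate the full set of metadata tables.

    Articles are assigned to topics uniformly at random; each article mentions
    entities drawn mostly from its topic's pool; citations point to
    earlier-indexed articles and stay within topic with probability
    ``citation_intra_topic_prob``; abstracts interleave the article's mention
    strings with filler tokens disjoint from all mention vocabulary.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))

    pmids = np.arange(1, config.n_articles + 1)
    topics = rng.integers(0, config.n_topics, size=config.n_articles)

    # entity catalogue: dense integer ids partitioned over (topic, type)
    entity_rows = []  # (entity_id, entity_type, topic, base_name)
    eid = 1
    for topic in range(config.n_topics):
        for etype in ENTITY_TYPES:
            for _ in range(config.entities_per_topic):
                entity_rows.append((eid, etype, topic, _entity_base_name(etype, eid)))
                eid += 1
    entity_ids = np.array([r[0] for r in entity_rows])
    topic_pools: dict[int, np.ndarray] = {
        t: np.array([r[0] for r in entity_rows if r[2] == t])
        for t in range(config.n_topics)
    }
    by_id = {r[0]: r for r in entity_rows}
    variants_by_id = {
        r[0]: _mention_variants(r[3], config.mention_variant_count)
        for r in entity_rows
    }

    # mentions
    mention_rows = []
    lo, hi = config.mentions_per_article
    for pmid, topic in zip(pmids, topics):
        n_m = int(rng.integers(lo, hi + 1))
        for _ in range(n_m):
            if rng.random() < INTRA_TOPIC_MENTION_PROB:
                e = int(rng.choice(topic_pools[int(topic)]))
            else:
                e = int(rng.choice(entity_ids))
            variant = variants_by_id[e][int(rng.integers(len(variants_by_id[e])))]
            mention_rows.append((int(pmid), e, by_id[e][1], variant))
    mentions = pd.DataFrame(
        mention_rows, columns=["pmid", "entity_id", "entity_type", "mention"]
    ).drop_duplicates(ignore_index=True)

    # articles: title + abstract token streams containing the mention strings
    mention_strings_per_pmid: dict[int, list[str]] = {
        int(p): g["mention"].tolist() for p, g in mentions.groupby("pmid")
    }
    art_rows = []
    for pmid, topic in zip(pmids, topics):
        fillers = [f"{_FILLER_PREFIX}{int(x):03d}" for x in rng.integers(0, 200, size=12)]
        ments = mention_strings_per_pmid.get(int(pmid), [])
        title = " ".join(fillers[:3] + ments[:1])
        body: list[str] = []
        for i, f in enumerate(fillers[3:]):
            body.append(f)
            if i < len(ments):
                body.append(ments[i])
        art_rows.append((int(pmid), title, " ".join(body), int(topic)))
    articles = pd.DataFrame(art_rows, columns=["pmid", "title", "abstract", "topic"])

    # authors: 1-3 per article
    author_rows = []
    for pmid in pmids:
        n_a = int(rng.integers(1, 4))
        aids = rng.choice(config.n_authors, size=min(n_a, config.n_authors),
                          replace=False) + 1
        for aid in aids:
            author_rows.append((int(pmid), int(aid), f"author_{int(aid)}"))
    authors = pd.DataFrame(author_rows, columns=["pmid", "aid", "name"])

    # citations: to earlier-indexed articles, intra-topic biased
    ref_rows = []
    clo, chi = config.citations_per_article
    earlier_by_topic: dict[int, list[int]] = {t: [] for t in range(config.n_topics)}
    earlier_all: list[int] = []
    for pmid, topic in zip(pmids, topics):
        n_c = int(rng.integers(clo, chi + 1))
        n_c = min(n_c, len(earlier_all))
        cited: set[int] = set()
        for _ in range(n_c):
            pool = earlier_by_topic[int(topic)]
            if rng.random() < config.citation_intra_topic_prob and pool:
                c = int(pool[int(rng.integers(len(pool)))])
            else:
                c = int(earlier_all[int(rng.integers(len(earlier_all)))])
            if c != int(pmid) and c not in cited:
                cited.add(c)
                ref_rows.append((int(pmid), c))
        earlier_by_topic[int(topic)].append(int(pmid))
        earlier_all.append(int(pmid))
    references = pd.DataFrame(ref_rows, columns=["pmid", "cited_pmid"])

    # project and MeSH links (possibly empty)
    proj_rows = []
    if config.n_projects > 0:
        for pmid in pmids:
            if rng.random() < 0.3:
                proj_rows.append((int(pmid), int(rng.integers(1, config.n_projects + 1))))
    projects = pd.DataFrame(proj_rows, columns=["pmid", "project_id"])

    mesh_rows = []
    if config.n_mesh > 0:
        for pmid in pmids:
            for h in rng.choice(config.n_mesh, size=2, replace=False) + 1:
                mesh_rows.append((int(pmid), int(h)))
    mesh = pd.DataFrame(mesh_rows, columns=["pmid", "header_id"])

    truth = (
        mentions[["entity_id", "pmid"]]
        .drop_duplicates()
        .sort_values(["entity_id", "pmid"], ignore_index=True)
    )

    return SynthTables(articles=articles, authors=authors, mentions=mentions,
                       references=references, projects=projects, mesh=mesh,
                       truth=truth)


def generate_query_set(
    tables: SynthTables, n_queries: int, seed: int
) -> list[tuple[str, set[int]]]:
    """Sample planted entity queries with their ground-truth relevant sets.

    Each query text is one surface mention string of a sampled entity; the
    relevant set is copied from the truth table. Entities with empty relevant
    sets cannot occur (truth is derived from mentions), so every emitted query
    has at least one relevant article.
    """
    if tables.mentions.empty:
        raise ValueError("tables contain no mentions; cannot build queries")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0FFEE]))
    entities = np.sort(tables.truth["entity_id"].unique())
    if n_queries > len(entities):
        raise ValueError(
            f"n_queries={n_queries} exceeds the {len(entities)} distinct entities")
    chosen = rng.choice(entities, size=n_queries, replace=False)
    relevant = {
        int(e): set(map(int, g["pmid"]))
        for e, g in tables.truth.groupby("entity_id")
    }
    out = []
    for e in chosen:
        surfaces = sorted(
            tables.mentions.loc[tables.mentions["entity_id"] == e, "mention"].unique())
        text = surfaces[int(rng.integers(len(surfaces)))]
        out.append((text, relevant[int(e)]))
    return out


def write_tables(tables: SynthTables, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.as_dict().items():
        df.to_csv(out / TABLE_FILENAMES[name], sep="\t", index=False)


def read_tables(in_dir: str | Path) -> SynthTables:
    d = Path(in_dir)
    frames = {}
    for name, fname in TABLE_FILENAMES.items():
        frames[name] = pd.read_csv(d / fname, sep="\t",
                                   keep_default_na=False,
                                   dtype=_READ_DTYPES.get(name))
    return SynthTables(**frames)


_READ_DTYPES: dict[str, dict] = {
    "articles": {"pmid": int, "title": str, "abstract": str, "topic": int},
    "authors": {"pmid": int, "aid": int, "name": str},
    "mentions": {"pmid": int, "entity_id": int, "entity_type": str, "mention": str},
    "references": {"pmid": int, "cited_pmid": int},
    "projects": {"pmid": int, "project_id": int},
    "mesh": {"pmid": int, "header_id": int},
    "truth": {"entity_id": int, "pmid": int},
}
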