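"""Pooling, query vectors, cosine ranking and end-to-end search."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from medgraph import (EmbeddingMatrix, SynthConfig, build_state,
                      generate_query_set, generate_tables)
from medgraph.pipeline import PipelineConfig
from medgraph.query import MatchSet, NoMatchError
from medgraph.retrieval import (ArticleVectors, article_embeddings, cosine,
                                embed_query, pool_neighbors, rank, search)


def star_graph():
    """One article linked to an author, a drug and two cited articles."""
    g = nx.MultiGraph()
    nodes = {
        "a1": "article/pmid/1", "a2": "article/pmid/2", "a3": "article/pmid/3",
        "auth": "author/aid/1", "drug": "bioentity/drug/1",
    }
    types = {"a1": "article", "a2": "article", "a3": "article",
             "auth": "author", "drug": "drug"}
    for k, nid in nodes.items():
        g.add_node(nid, node_type=types[k])
    g.add_edge(nodes["a1"], nodes["auth"], key="w", label="w")
    g.add_edge(nodes["a1"], nodes["drug"], key="m", label="m")
    g.add_edge(nodes["a1"], nodes["a2"], key="c", label="c")
    g.add_edge(nodes["a1"], nodes["a3"], key="c", label="c")
    return g, nodes


def vectors_for(nodes, mapping):
    names = sorted(nodes.values())
    return EmbeddingMatrix(names, np.array([mapping[n] for n in names], float))


class TestPooling:
    def test_mean_of_two_neighbors(self):
        g, n = star_graph()
        emb = vectors_for(n, {
            n["a1"]: [0, 0], n["a2"]: [1, 1], n["a3"]: [3, 3],
            n["auth"]: [5, 5], n["drug"]: [7, 7]})
        out = pool_neighbors(g, emb, n["a1"], neighbor_types={"article"})
        assert np.allclose(out, [2, 2])

    def test_single_neighbor_identity(self):
        g, n = star_graph()
        emb = vectors_for(n, {
            n["a1"]: [0, 0], n["a2"]: [1, 2], n["a3"]: [3, 3],
            n["auth"]: [5, 5], n["drug"]: [7, 7]})
        out = pool_neighbors(g, emb, n["a2"])
        assert np.allclose(out, [0, 0])  # a2's only neighbor is a1

    def test_all_type_pooling(self):
        g, n = star_graph()
        emb = vectors_for(n, {
            n["a1"]: [100, 100], n["a2"]: [1, 0], n["a3"]: [3, 0],
            n["auth"]: [5, 0], n["drug"]: [7, 0]})
        out = pool_neighbors(g, emb, n["a1"])
        assert np.allclose(out, [4, 0])

    def test_include_self(self):
        g, n = star_graph()
        emb = vectors_for(n, {
            n["a1"]: [8, 0], n["a2"]: [0, 0], n["a3"]: [0, 0],
            n["auth"]: [0, 0], n["drug"]: [0, 0]})
        out = pool_neighbors(g, emb, n["a1"], include_self=True)
        assert np.allclose(out, [8 / 5, 0])

    def test_no_selection_raises(self):
        g, n = star_graph()
        emb = vectors_for(n, {k: [1, 1] for k in n.values()})
        with pytest.raises(ValueError):
            pool_neighbors(g, emb, n["a2"], neighbor_types={"author"})

    def test_permutation_invariance_identical_vectors(self):
        g, n = star_graph()
        emb = vectors_for(n, {k: [2.5, -1] for k in n.values()})
        assert np.allclose(pool_neighbors(g, emb, n["a1"]), [2.5, -1])


class TestArticleEmbeddings:
    def test_two_stage_semantics(self):
        g, n = star_graph()
        emb = vectors_for(n, {
            n["a1"]: [0, 0], n["a2"]: [2, 0], n["a3"]: [4, 0],
            n["auth"]: [6, 0], n["drug"]: [8, 0]})
        av = article_embeddings(g, emb, targets=set(
            [n["a1"], n["a2"], n["a3"]]))
        # stage 1: a1 <- mean(auth, drug, a2, a3) = [5, 0]; a2, a3 <- a1's raw [0, 0]
        # stage 2: a1 <- mean(stage1[a2], stage1[a3]) = [0, 0]
        #          a2 <- stage1[a1] = [5, 0] (its only article neighbor)
        assert np.allclose(av.vectors[n["a1"]], [0, 0])
        assert np.allclose(av.vectors[n["a2"]], [5, 0])
        assert av.stage == "stage2"

    def test_uncited_target_falls_back_to_stage1(self):
        g = nx.MultiGraph()
        a, auth = "article/pmid/9", "author/aid/9"
        g.add_node(a, node_type="article")
        g.add_node(auth, node_type="author")
        g.add_edge(a, auth, key="w", label="w")
        emb = EmbeddingMatrix([a, auth], np.array([[1.0, 1.0], [3.0, 5.0]]))
        av = article_embeddings(g, emb, targets={a})
        assert np.allclose(av.vectors[a], [3, 5])

    def test_missing_target_listed(self):
        g, n = star_graph()
        emb = vectors_for(n, {k: [1, 1] for k in n.values()})
        with pytest.raises(KeyError, match="article/pmid/99"):
            article_embeddings(g, emb, targets={"article/pmid/99"})


class TestQueryVector:
    def make_emb(self):
        return EmbeddingMatrix(["bioentity/drug/1", "bioentity/drug/2"],
                               np.array([[0.0, 2.0], [2.0, 0.0]]))

    def test_single_entity_identity(self, small_tables):
        from medgraph import build_index
        idx = build_index(small_tables.mentions)
        eid = next(iter(idx.entity_to_articles))
        nid = idx.node_id(eid)
        emb = EmbeddingMatrix([nid], np.array([[1.0, 2.0, 3.0]]))
        ms = MatchSet(matched=[("kw", eid, 0)])
        assert np.allclose(embed_query(ms, emb, idx), [1, 2, 3])

    def test_mean_of_two_entities(self):
        from medgraph.kg import EntityIndex
        idx = EntityIndex(mention_to_entity={"a": 1, "b": 2},
                          entity_type={1: "drug", 2: "drug"},
                          entity_to_articles={1: {1}, 2: {2}})
        ms = MatchSet(matched=[("a", 1, 0), ("b", 2, 0)])
        assert np.allclose(embed_query(ms, self.make_emb(), idx), [1, 1])

    def test_empty_match_raises(self):
        from medgraph.kg import EntityIndex
        with pytest.raises(NoMatchError):
            embed_query(MatchSet(), self.make_emb(), EntityIndex())


class TestCosine:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 0], [0, 1], 0.0),
        ([2, 2], [1, 1], 1.0),
        ([1, 2, 3], [4, 5, 6], 0.974632),
    ])
    def test_known_values(self, a, b, expected):
        assert cosine(np.array(a, float), np.array(b, float)) == \
            pytest.approx(expected, abs=1e-5)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine(np.zeros(3), np.ones(3))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(arrays(np.float64, 5, elements=st.floats(-5, 5)),
           arrays(np.float64, 5, elements=st.floats(-5, 5)),
           st.floats(0.1, 10))
    def test_properties(self, a, b, scale):
        if np.linalg.norm(a) < 1e-9 or np.linalg.norm(b) < 1e-9:
            return
        c = cosine(a, b)
        assert -1.0 <= c <= 1.0
        assert c == pytest.approx(cosine(b, a))
        assert c == pytest.approx(cosine(scale * a, b), abs=1e-9)
        assert c == pytest.approx(
            float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b))), abs=1e-9)


def make_av(vectors: dict[int, list[float]]) -> ArticleVectors:
    vecs = {f"article/pmid/{p}": np.array(v, float) for p, v in vectors.items()}
    return ArticleVectors(vectors=vecs, stage="stage2", targets=set(vecs))


class TestRank:
    def test_k_exceeding_targets_returns_all(self):
        av = make_av({1: [1, 0], 2: [0, 1]})
        out = rank(np.array([1.0, 0.5]), av, k=10)
        assert len(out.items) == 2

    def test_equal_scores_lower_pmid_first(self):
        av = make_av({7: [1, 0], 3: [1, 0]})
        out = rank(np.array([1.0, 0.0]), av, k=2)
        assert out.pmids == [3, 7]

    def test_identical_vector_ranks_first_with_score_one(self):
        av = make_av({1: [0, 1], 2: [1, 0], 3: [0, -1]})
        out = rank(np.array([0.0, 1.0]), av, k=3)
        assert out.pmids[0] == 1
        assert out.items[0][1] == pytest.approx(1.0)

    def test_topk_is_prefix_of_larger_k(self):
        rng = np.random.default_rng(0)
        av = make_av({p: rng.normal(size=4).tolist() for p in range(1, 30)})
        q = rng.normal(size=4)
        small = rank(q, av, k=5).pmids
        big = rank(q, av, k=20).pmids
        assert big[:5] == small

    def test_scores_non_increasing(self):
        rng = np.random.default_rng(1)
        av = make_av({p: rng.normal(size=3).tolist() for p in range(1, 20)})
        out = rank(rng.normal(size=3), av, k=19)
        scores = [s for _, s in out.items]
        assert all(x >= y for x, y in zip(scores, scores[1:]))


@pytest.fixture(scope="module")
def tiny_state():
    cfg = PipelineConfig.from_dict({
        "seed": 5,
        "synth": {"n_articles": 60, "n_topics": 3},
        "embedding": {"dim": 24, "epochs": 3, "walk_length": 20,
                      "walks_per_node": 3},
    })
    tables = generate_tables(cfg.synth)
    return cfg, tables, build_state(tables, cfg)


class TestSearch:
    def test_unmatched_query_is_clean_no_results(self, tiny_state):
        _, _, state = tiny_state
        with pytest.raises(NoMatchError):
            search("qqqqqqqq wwwwwwww", state, k=5)

    def test_planted_mention_scores_all_relevant(self, tiny_state):
        cfg, tables, state = tiny_state
        text, relevant = generate_query_set(tables, 1, seed=1)[0]
        out1 = search(text, state, k=len(state.article_vectors.vectors))
        out2 = search(text, state, k=len(state.article_vectors.vectors))
        assert out1.items == out2.items  # deterministic rerun
        scored = dict(out1.items)
        assert all(p in scored and np.isfinite(scored[p]) for p in relevant)

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_relevant_articles_score_above_nonrelevant(self, seed):
        cfg = PipelineConfig.from_dict({
            "seed": seed,
            "synth": {"n_articles": 100, "n_topics": 4},
            "embedding": {"dim": 32, "epochs": 3, "walk_length": 20,
                          "walks_per_node": 3},
        })
        tables = generate_tables(cfg.synth)
        state = build_state(tables, cfg)
        margins = []
        for text, relevant in generate_query_set(tables, 5, seed=seed):
            out = search(text, state, k=10 ** 6)
            rel = [s for p, s in out.items if p in relevant]
            non = [s for p, s in out.items if p not in relevant]
            margins.append(np.mean(rel) - np.mean(non))
        assert np.mean(margins) > 0
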