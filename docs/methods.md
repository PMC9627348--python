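# Methods

## The model

The ranker embeds a heterogeneous metadata graph into Euclidean space and
reduces retrieval to nearest-neighbor search. The key assumption is that
relevance is encoded by graph proximity: an article that mentions an entity,
cites articles that mention it, or shares authors/MeSH context with such
articles, ends up near that entity's node vector. The embedding is purely
structural — edge labels and node types are ignored during walking, so the
model cannot distinguish *why* two nodes are close (a conceded limitation of
this family of embeddings; heterogeneity-aware models are out of scope).

### Graph construction

One triple per deduplicated metadata statement; duplicate triples (e.g. two
surface strings of one entity in one article) collapse to a single labeled
undirected edge. Nine node types and nine edge labels are supported; node
type is a pure function of the id prefix (`article/pmid/...`,
`author/aid/...`, `bioentity/drug/...`). Authorship is modeled as an edge
label like any other relation. The entity index maps normalized mention
strings (case-folded, punctuation stripped, whitespace collapsed) to entity
ids and entity ids to the articles mentioning them; when two entities claim
the same normalized surface form the first table row wins, deterministically.

### Walks and skip-gram

Second-order walks with return bias p and in-out bias q (weight 1/p to
revisit the previous node, 1 for its neighbors, 1/q for nodes two steps
away). p and q follow the standard definition of the biased-walk algorithm;
q < 1 pushes walks outward, which the test suite verifies directly on a
star-of-paths graph. Walks truncate at dead ends rather than padding —
isolated nodes still receive a (purely initialization-driven) vector.

Skip-gram with negative sampling is implemented in-package (the training
loop is the method's core, and no suitable embedding library is part of the
supported stack): sequential SGD over all (center, context) pairs with
|offset| ≤ window, `negatives` noise draws per pair from the unigram
distribution raised to 0.75 (the skip-gram convention; the source model
leaves the noise distribution unspecified), learning rate decaying linearly
from 0.025 to 1e-4, input vectors initialized uniform in ±0.5/d, output
vectors at zero, logits clipped at ±12. The inner loop is numba-compiled;
the pure-Python kernel is the reference semantics and the compiled function
is the same code, so results are identical either way. Training is
single-threaded by construction, which is what makes byte-identical
reruns possible.

Hyperparameter defaults (d=128, window 5, 7 negatives, p=2, q=0.5, walk
length 50, 5 walks per node) are the tuned values of the reference
configuration. Epoch count and learning rate were never published for the
original system; 5 epochs and the word2vec-standard schedule are this
package's choices.

### Pooling, query vectors, ranking

Stage 1 averages *all* first-order neighbors of every article; stage 2
averages the stage-1 vectors of an article's citation neighbors only. The
two readings of the pooling operation in the source material (all-type vs
article-only) are reconciled by using each exactly once, and both filters
remain configurable in `pool_neighbors`. The article's own vector is not
included at either stage; degenerate nodes (no neighbors / no citations)
fall back to their own raw or stage-1 vector respectively. Query vectors
average the *raw* node vectors of matched entities, not pooled article
vectors. Ranking is cosine similarity with ties broken by ascending PMID so
that runs are reproducible.

Query matching uses Levenshtein distance with a default threshold of 1 — 
tight enough not to conflate short entity names, loose enough for the
plural/suffix variants the generator plants. Distance is computed with the
`edlib` aligner; the test suite checks it against a full dynamic-programming
oracle. Verb removal is available behind a flag using a small lexicon of
imperative search verbs (no POS tagger is part of the supported stack) and
is off by default, keeping the core pipeline deterministic and
dependency-light. The sliding-window expansion defaults to sizes {2, 3, 4};
the worked example in the documentation uses {2, 3}, and both are exposed.

### Evaluation

Standard definitions: precision@K = hits / retrieved, recall@K = hits /
|relevant|, F1 their harmonic mean. (Some descriptions of this protocol
swap the two words; the standard forms are implemented.) Average precision
ships in two variants — `standard` (mean precision at relevant retrieved
positions, normalized by min(|relevant|, K)) and `all_positions` (mean of
precision over every retrieved position up to K, a literal reading of the
protocol's prose) — with `standard` the default. Queries whose ranker
output is empty (or whose ranker raises) score 0 on all metrics, keeping
means well-defined. Ground-truth pruning truncates each judgment list to its
first K entries before scoring. The default K grid is
{1, 2, 5, 10, 25, 50, 75, 100, 150, 250, 500, 1000}.

## The synthetic corpus

The generator emulates the relational shape of a PubMed metadata export:
seven TSV tables joined by PMID. Planted structure: articles are assigned
topics uniformly; each article draws 2–5 entity mentions, 80% from its own
topic's entity pool (module constant — a value high enough that topics are
recoverable but with enough leakage that cross-topic edges exist); citations
go to earlier-indexed articles, within topic with probability 0.8 by
default; each entity has three deterministic surface variants (base,
case-changed, distance-1 suffixed) so normalization and fuzzy matching are
both exercised; abstracts interleave mention strings with filler tokens
drawn from a vocabulary disjoint from all mention strings, so the TF-IDF
baseline's behavior is analyzable. Ground truth for an entity query is
exactly the set of articles whose mention table contains that entity.

What the generator does **not** emulate: realistic citation-age or degree
distributions, author-name ambiguity, entity-mention synonymy beyond the
deterministic variants, or abstract language with distributional structure.
Consequently, passing the planted-signal tests shows the pipeline recovers
structure it was pointed at; it does not certify ranking quality on real
PubMed data, where ground truth came from a proprietary-scale corpus and a
live relevance reference. The benchmark scale used throughout (200 articles,
4 topics, 12 planted queries, ~430 graph nodes) is the package's chosen
desk-scale condition; metrics at this scale show the qualitative pattern —
strong TF-IDF early precision (mentions appear verbatim in abstracts),
stronger embedding-ranker recall at large K through citation structure —
rather than reproducing any published absolute numbers.

## Numerical and design notes

- All randomness derives from one config seed through fixed per-stage
  substreams (generator, walks/SGD, query sampling); two runs with the same
  config are byte-identical on disk, which the acceptance suite asserts.
- Cosine is clipped into [−1, 1] against floating-point drift and raises on
  zero vectors; callers with degenerate vectors must handle that explicitly.
- TF-IDF uses plain log(N/df) with no add-one smoothing; zero-idf terms are
  retained (they simply carry no weight). One consequence worth knowing:
  documents that differ only in the multiplicity of a shared term collapse
  to the same unit vector after L2 normalization and tie under cosine; ties
  resolve by ascending PMID.
- Matching keywords that hit no entity are dropped silently as long as at
  least one keyword matches; only a fully unmatched query is the "no
  results" exit (exit code 2 on the CLI, `NoMatchError` in the API).
- Known limitations: structure-only embeddings (no edge-label awareness),
  O(|index|) linear scan per fuzzy keyword lookup (fine at desk scale),
  and no approximate-nearest-neighbor index for ranking.
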