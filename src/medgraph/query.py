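"""Free-text query processing: tokenize, sliding-window expansion, and fuzzy
matching of keywords against the bio-entity index.

A query like ``"show me articles on depression and type 2 diabetes"`` is
reduced to its content tokens, expanded with contiguous n-grams (window sizes
2-4 by default) so that multi-word entity names are recoverable, and each
keyword is matched to the entity index by Levenshtein distance.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

import edlib

from .kg import EntityIndex, normalize_mention

__all__ = [
    "TokenizedQuery",
    "ExpandedQuery",
    "MatchSet",
    "NoMatchError",
    "DEFAULT_STOPWORDS",
    "tokenize",
    "expand",
    "match",
    "levenshtein",
]

#: small built-in English stop-word list (query glue words and common
#: imperative search phrasing); replaceable per call
DEFAULT_STOPWORDS = frozenset("""
a about all an and any are as at be been but by can could did do does for
from get give had has have how i if in into is it its me my of on or our
over please s she he so some such show than that the their them then there
these they this those to us was we were what when where which who will with
would you your find search list
""".split())

#: common imperative/search verbs removed when the optional verb filter is on
_VERB_LEXICON = frozenset("""
show find search retrieve list give get fetch display bring locate identify
describe explain compare summarize
""".split())


@dataclass
class TokenizedQuery:
    raw: str
    tokens: list[str]


@dataclass
class ExpandedQuery:
    keywords: list[str]


@dataclass
class MatchSet:
    matched: list[tuple[str, int, int]] = field(default_factory=list)  # (keyword, entity_id, distance)
    unmatched: list[str] = field(default_factory=list)

    @property
    def entity_ids(self) -> list[int]:
        return [e for _, e, _ in self.matched]


class NoMatchError(LookupError):
    """No keyword of the query matched any indexed entity."""


_PUNCT_TABLE = str.maketrans({c: " " for c in string.punctuation})


def tokenize(text: str, stopwords: frozenset[str] | set[str] = DEFAULT_STOPWORDS,
             verb_filter: bool = False) -> TokenizedQuery:
    """Lower-case, strip punctuation, split on whitespace, drop stop words
    (and, optionally, common search verbs). Order is preserved. An all-stop-word
    query yields an empty token list; downstream reports no match."""
    if not text or not text.strip():
        raise ValueError("query text is empty")
    cleaned = text.casefold().translate(_PUNCT_TABLE)
    tokens = [t for t in cleaned.split() if t not in stopwords]
    if verb_filter:
        tokens = [t for t in tokens if t not in _VERB_LEXICON]
    return TokenizedQuery(raw=text, tokens=tokens)


def expand(tq: TokenizedQuery, windows: set[int] = frozenset({2, 3, 4})) -> ExpandedQuery:
    """Original tokens followed by all contiguous w-grams (space-joined) for
    each window size in ascending order; within a size, left to right.

    For n tokens, |keywords| = n + sum over fitting w of (n - w + 1).
    """
    tokens = tq.tokens
    keywords = list(tokens)
    for w in sorted(windows):
        if w < 1:
            raise ValueError("window sizes must be >= 1")
        for i in range(len(tokens) - w + 1):
            keywords.append(" ".join(tokens[i:i + w]))
    return ExpandedQuery(keywords=keywords)


def levenshtein(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions and
    substitutions transforming ``a`` into ``b``."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance")["editDistance"]


def match(eq: ExpandedQuery, index: EntityIndex, max_distance: int = 1) -> MatchSet:
    """Match each keyword to the minimum-Levenshtein-distance index mention.

    Keywords are normalized exactly like index keys; an exact hit short-circuits
    the scan. Ties break toward the lexicographically smallest mention string.
    Duplicate entity ids collapse (first keyword wins). An all-unmatched query
    returns an empty ``matched`` list; callers treat that as the no-results
    exit (see :class:`NoMatchError`).
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    mentions = sorted(index.mention_to_entity)
    out = MatchSet()
    seen_entities: set[int] = set()
    for kw in eq.keywords:
        key = normalize_mention(kw)
        if not key:
            out.unmatched.append(kw)
            continue
        if key in index.mention_to_entity:
            best_mention, best_d = key, 0
        else:
            best_mention, best_d = None, max_distance + 1
            for m in mentions:
                d = levenshtein(key, m)
                if d < best_d:  # strict: earlier (lexicographically smaller) wins ties
                    best_mention, best_d = m, d
        if best_mention is not None and best_d <= max_distance:
            eid = index.mention_to_entity[best_mention]
            if eid not in seen_entities:
                seen_entities.add(eid)
                out.matched.append((kw, eid, best_d))
        else:
            out.unmatched.append(kw)
    return out
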