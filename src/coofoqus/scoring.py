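"""The score keeper: similarity backends and per-triple score assembly.

Two interchangeable backends rate how well a triple's rendered labels
match a question's phrases:

* ``string`` — Monge-Elkan token-set similarity with a normalized
  Smith-Waterman-Gotoh local character alignment as the inner metric
  (match +1, mismatch -1, gap -0.5 with gap open equal to gap extend,
  score divided by the longer string's self-alignment score);
* ``vector`` — cosine similarity of mean word vectors from a
  pluggable embedding table.

Raw backend scores are then adjusted with a WordNet-style lexical
relation resource: a synonym pair (within a bounded graph depth) boosts
the score by 25%, the absence of any synonym/hypernym/hyponym relation
zeroes it, and any other relation leaves it unchanged. Every emitted
score lies in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .kb_model import AssertionTriple
from .question_analysis import ParsedQuestion, clean_terms, lemmatize, _tokenize

__all__ = [
    "SimilarityBackend",
    "TripleScore",
    "EmbeddingTable",
    "LexicalRelations",
    "swg_similarity",
    "monge_elkan",
    "vector_similarity",
    "lexical_adjust",
    "score_triple",
    "score_assertions",
]


class SimilarityBackend(enum.Enum):
    STRING = "string"
    VECTOR = "vector"


# ------------------------------------------------------------------ string

def swg_similarity(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -0.5,
) -> float:
    """Normalized Smith-Waterman-Gotoh local alignment over characters.

    Gap open equals gap extend (linear gaps), so the affine recurrence
    collapses to the single-matrix local-alignment form. The best local
    score is divided by ``match * max(|a|, |b|)`` — the longer string's
    self-alignment — and clamped to [0, 1]. Either string empty -> 0.
    """
    if not a or not b:
        return 0.0
    n, m = len(a), len(b)
    prev = [0.0] * (m + 1)
    best = 0.0
    for i in range(1, n + 1):
        cur = [0.0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            sub = match if ai == b[j - 1] else mismatch
            score = max(0.0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = score
            if score > best:
                best = score
        prev = cur
    return min(1.0, max(0.0, best / (match * max(n, m))))


def monge_elkan(
    tokens_a: Sequence[str],
    tokens_b: Sequence[str],
    inner: Callable[[str, str], float] = swg_similarity,
) -> float:
    """Asymmetric Monge-Elkan: mean over ``tokens_a`` of the best inner
    similarity in ``tokens_b``. Empty ``tokens_a`` or ``tokens_b`` -> 0."""
    if not tokens_a or not tokens_b:
        return 0.0
    total = 0.0
    for ta in tokens_a:
        total += max(inner(ta, tb) for tb in tokens_b)
    return min(1.0, max(0.0, total / len(tokens_a)))


# ------------------------------------------------------------------ vector

class EmbeddingTable:
    """Fixed-dimension word vectors keyed by (lemmatized) term.

    File format: one term per line, ``term v1 v2 ... vd``. All rows must
    share one dimension; a mismatch is a configuration error.
    """

    def __init__(self, vectors: dict[str, Sequence[float]]):
        dims = {len(v) for v in vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"embedding table has mixed dimensions: {sorted(dims)}")
        self.dim = dims.pop() if dims else 0
        self.vectors = {t: np.asarray(v, dtype=float) for t, v in vectors.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "EmbeddingTable":
        vectors: dict[str, list[float]] = {}
        for line in Path(path).read_text("utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            vectors[parts[0]] = [float(x) for x in parts[1:]]
        return cls(vectors)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def mean_vector(self, terms: Iterable[str]) -> np.ndarray | None:
        vecs = [self.vectors[t] for t in terms if t in self.vectors]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)


def vector_similarity(
    terms_a: Sequence[str], terms_b: Sequence[str], embeddings: EmbeddingTable
) -> float:
    """Cosine of the mean vectors of two term lists, clamped to [0, 1].

    Out-of-vocabulary terms are skipped; if either side has no
    in-vocabulary term the similarity is 0.
    """
    va = embeddings.mean_vector(terms_a)
    vb = embeddings.mean_vector(terms_b)
    if va is None or vb is None:
        return 0.0
    na, nb = float(np.linalg.norm(va)), float(np.linalg.norm(vb))
    if na == 0.0 or nb == 0.0:
        return 0.0
    return min(1.0, max(0.0, float(va @ vb) / (na * nb)))


# ----------------------------------------------------------------- lexicon

class LexicalRelations:
    """Synonym/hypernym/hyponym lookup over word pairs with depth bounds.

    Entries are (term1, relation, term2, depth) with relation in
    {syn, hyper, hypo}; synonymy is symmetric, and hyper(a, b) is the
    inverse of hypo(b, a). A term is synonymous with itself at depth 0
    (a word shares a synset with itself), so exact term matches always
    take the synonym branch.
    """

    def __init__(self, entries: Iterable[tuple[str, str, str, int]] = ()):
        self._syn: dict[frozenset[str], int] = {}
        self._hier: set[frozenset[str]] = set()
        for t1, rel, t2, depth in entries:
            self.add(t1, rel, t2, depth)

    def add(self, term1: str, relation: str, term2: str, depth: int = 1) -> None:
        if relation not in {"syn", "hyper", "hypo"}:
            raise ValueError(f"unknown lexical relation: {relation!r}")
        if depth < 1:
            raise ValueError("relation depth must be >= 1")
        pair = frozenset((term1.lower(), term2.lower()))
        if relation == "syn":
            prev = self._syn.get(pair)
            self._syn[pair] = depth if prev is None else min(prev, depth)
        else:
            self._hier.add(pair)

    @classmethod
    def from_file(cls, path: str | Path) -> "LexicalRelations":
        """Parse ``term1<TAB>relation<TAB>term2<TAB>depth`` lines."""
        lex = cls()
        for raw in Path(path).read_text("utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            t1, rel, t2, depth = line.split("\t")
            lex.add(t1, rel, t2, int(depth))
        return lex

    def synonymous(self, a: str, b: str, max_depth: int = 3) -> bool:
        a, b = a.lower(), b.lower()
        if a == b:
            return True
        depth = self._syn.get(frozenset((a, b)))
        return depth is not None and depth <= max_depth

    def related(self, a: str, b: str) -> bool:
        """Any synonym / hypernym / hyponym link at any recorded depth."""
        a, b = a.lower(), b.lower()
        if a == b:
            return True
        pair = frozenset((a, b))
        return pair in self._syn or pair in self._hier


def lexical_adjust(
    score: float,
    terms_a: Sequence[str],
    terms_b: Sequence[str],
    lex: LexicalRelations,
    boost: float = 1.25,
    synonym_depth: int = 3,
) -> float:
    """Apply the lexical-relation rule to a backend score.

    Any synonymous cross-pair (within the depth bound) -> score * boost,
    capped at 1. No cross-pair with any relation at all -> 0. Otherwise
    the score is left as is. Terms absent from the resource count as
    unrelated.
    """
    pairs = [(a, b) for a in terms_a for b in terms_b]
    if any(lex.synonymous(a, b, synonym_depth) for a, b in pairs):
        return min(1.0, boost * score)
    if not any(lex.related(a, b) for a, b in pairs):
        return 0.0
    return score


# ----------------------------------------------------------- triple scores

@dataclass
class TripleScore:
    triple: AssertionTriple
    predicate_score: float | None
    entity_score: float
    combined: float


def _label_terms(label: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Cleaned terms of a triple label, never empty for a non-empty label.

    Labels are content terms by construction, so when stop-listing
    empties the cleaned list (e.g. the class label "people"), the
    lemmatized raw tokens are used instead.
    """
    terms = clean_terms(label, stopwords)
    if terms:
        return terms
    out: list[str] = []
    for tok in _tokenize(label):
        root = lemmatize(tok)
        if root not in out:
            out.append(root)
    return out


def _backend_sim(
    triple_terms: Sequence[str],
    phrase_terms: Sequence[str],
    backend: SimilarityBackend,
    embeddings: EmbeddingTable | None,
    swg_params: dict | None,
) -> float:
    if backend is SimilarityBackend.VECTOR:
        if embeddings is None:
            raise ValueError("vector backend requires an embedding table")
        return vector_similarity(triple_terms, phrase_terms, embeddings)
    params = swg_params or {}
    inner = lambda x, y: swg_similarity(x, y, **params)  # noqa: E731
    return monge_elkan(triple_terms, phrase_terms, inner)


def score_triple(
    triple: AssertionTriple,
    question: ParsedQuestion,
    lex: LexicalRelations,
    backend: SimilarityBackend = SimilarityBackend.STRING,
    embeddings: EmbeddingTable | None = None,
    boost: float = 1.25,
    synonym_depth: int = 3,
    swg_params: dict | None = None,
    entity_aggregation: str = "max",
    stopwords: frozenset[str] | None = None,
) -> TripleScore:
    """Score one triple against a parsed question.

    The predicate label is compared with the verb phrases (best phrase
    wins); when the question has no verb phrase the predicate comparison
    is skipped and the combined score is the entity score alone. The
    subject and object labels are compared with the noun phrases and
    aggregated (max by default, mean optionally). Each individual
    comparison is lexically adjusted before aggregation, and the
    combined score is the mean of predicate and entity scores.
    """
    dom_label, prop_label, rng_label = triple.labels()

    def adjusted(label: str, phrase: Sequence[str]) -> float:
        terms = _label_terms(label, stopwords)
        raw = _backend_sim(terms, phrase, backend, embeddings, swg_params)
        return lexical_adjust(raw, terms, phrase, lex, boost, synonym_depth)

    predicate_score: float | None = None
    if question.verb_phrases:
        predicate_score = max(adjusted(prop_label, vp) for vp in question.verb_phrases)

    entity_labels = [dom_label, rng_label]
    pair_scores = [
        adjusted(label, np_)
        for label in entity_labels
        for np_ in question.noun_phrases
    ]
    if not pair_scores:
        entity_score = 0.0
    elif entity_aggregation == "mean":
        entity_score = sum(pair_scores) / len(pair_scores)
    else:
        entity_score = max(pair_scores)

    if predicate_score is None:
        combined = entity_score
    else:
        combined = (predicate_score + entity_score) / 2.0
    return TripleScore(triple, predicate_score, entity_score, combined)


def score_assertions(
    triples: Iterable[AssertionTriple],
    question: ParsedQuestion,
    lex: LexicalRelations,
    backend: SimilarityBackend = SimilarityBackend.STRING,
    embeddings: EmbeddingTable | None = None,
    **kwargs,
) -> list[TripleScore]:
    """Score a family of triples, in deterministic input order."""
    return [
        score_triple(t, question, lex, backend, embeddings, **kwargs) for t in triples
    ]
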