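"""Candidate filtering, type-specific selection, and verbalization.

The selection cascade over scored instance triples:

1. threshold/rank gate — if the best object-property score exceeds 50%,
   keep the top 20% (by rank, boundary ties included) of the object+data
   triples; otherwise keep everything scoring above 45%;
2. question-type filter — numeric-content filter for COUNT/MAX/MIN (and
   NUMERIC) questions; otherwise a schema cross-check that keeps a
   candidate only when one of the class assertions it instantiates sits
   in the top 20% of the scored class assertions;
3. verbalization — surviving triples are rendered as short clauses in
   score order, or an explicit no-answer marker is returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .kb_model import AssertionKind, AssertionTriple, KnowledgeBase, tbox_assertions_of
from .question_analysis import (
    QuestionType,
    _tokenize,
    parse_question,
)
from .scoring import (
    EmbeddingTable,
    LexicalRelations,
    SimilarityBackend,
    TripleScore,
    score_assertions,
)

__all__ = [
    "FilterConfig",
    "Answer",
    "NO_ANSWER_LINE",
    "select_candidates",
    "numeric_filter",
    "class_assertion_filter",
    "render_answer",
    "answer_question",
]

NO_ANSWER_LINE = "I'm sorry, I don't have an answer for that one."

_DEFAULT_NUMBER_WORDS = (
    "one", "two", "three", "four", "five", "six", "seven", "eight", "nine", "ten",
)


@dataclass
class FilterConfig:
    top_gate: float = 0.50
    top_fraction: float = 0.20
    fallback_threshold: float = 0.45
    max_triples: int = 3
    permissive_class_filter: bool = False
    number_words: tuple[str, ...] = _DEFAULT_NUMBER_WORDS

    def __post_init__(self) -> None:
        if not (0.0 < self.fallback_threshold < self.top_gate <= 1.0):
            raise ValueError("require 0 < fallback_threshold < top_gate <= 1")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("require 0 < top_fraction <= 1")


@dataclass
class Answer:
    selected: list[AssertionTriple]
    text: str
    answered: bool
    qtype: QuestionType = QuestionType.UNKNOWN
    scores: list[TripleScore] = field(default_factory=list)
    class_scores: list[TripleScore] = field(default_factory=list)


def _sort_key(ts: TripleScore) -> tuple:
    # descending score; IRI triple as a deterministic tie-break
    rng = ts.triple.range if isinstance(ts.triple.range, str) else ts.triple.range.iri
    return (-ts.combined, ts.triple.domain.iri, ts.triple.property.iri, rng)


def _top_fraction(scored: list[TripleScore], fraction: float) -> list[TripleScore]:
    """Top ``ceil(fraction * N)`` by combined score, boundary ties included."""
    if not scored:
        return []
    ranked = sorted(scored, key=_sort_key)
    k = math.ceil(fraction * len(ranked))
    cutoff = ranked[k - 1].combined
    return [ts for ts in ranked if ts.combined >= cutoff]


def select_candidates(scored: list[TripleScore], cfg: FilterConfig) -> list[TripleScore]:
    """Threshold/rank gate over object- and data-property scores.

    ``scored`` should hold the object- and data-property families. When
    the best object-property combined score exceeds ``top_gate``, the
    top ``top_fraction`` of all object+data triples (by rank, ties at
    the boundary included) is returned; otherwise every triple with
    combined score above ``fallback_threshold``. Output is in
    descending score order.
    """
    object_scores = [
        ts.combined for ts in scored if ts.triple.kind is AssertionKind.OBJECT_PROPERTY
    ]
    top = max(object_scores, default=0.0)
    if top > cfg.top_gate:
        return _top_fraction(scored, cfg.top_fraction)
    return sorted(
        (ts for ts in scored if ts.combined > cfg.fallback_threshold), key=_sort_key
    )


def _has_numeric_content(label: str, number_words: tuple[str, ...]) -> bool:
    for tok in _tokenize(label):
        if any(ch.isdigit() for ch in tok) or tok in number_words:
            return True
    return False


def numeric_filter(
    candidates: list[TripleScore], cfg: FilterConfig | None = None
) -> list[TripleScore]:
    """Keep candidates whose rendered labels carry numerical content.

    A digit anywhere, or a number word ("one" ... "ten" by default) as a
    whole token, in any of the three label positions qualifies.
    """
    cfg = cfg or FilterConfig()
    return [
        ts
        for ts in candidates
        if any(_has_numeric_content(lbl, cfg.number_words) for lbl in ts.triple.labels())
    ]


def class_assertion_filter(
    candidates: list[TripleScore],
    class_scored: list[TripleScore],
    kb: KnowledgeBase,
    cfg: FilterConfig | None = None,
) -> list[TripleScore]:
    """Schema cross-check against the best-scoring class assertions.

    The top ``top_fraction`` of the scored class assertions forms the
    admissible set T; a candidate survives iff one of the class
    assertions it instantiates (via the type/subclass structure) is in
    T. With no class assertions at all the strict reading drops every
    candidate; ``permissive_class_filter`` passes them all instead.
    """
    cfg = cfg or FilterConfig()
    if not class_scored:
        return list(candidates) if cfg.permissive_class_filter else []
    admissible = {ts.triple for ts in _top_fraction(class_scored, cfg.top_fraction)}
    return [
        ts
        for ts in candidates
        if any(ca in admissible for ca in tbox_assertions_of(kb, ts.triple))
    ]


def render_answer(selected: list[AssertionTriple], no_answer_line: str = NO_ANSWER_LINE) -> str:
    """Verbalize triples as "<domain> <property> <range>" clauses.

    The first clause is sentence-cased, clauses join with "; also, ",
    and the answer ends with a period. Empty input yields the fixed
    no-answer line.
    """
    if not selected:
        return no_answer_line
    clauses = [" ".join(part for part in t.labels() if part) for t in selected]
    text = "; also, ".join(clauses)
    return text[0].upper() + text[1:] + "."


def answer_question(
    question: str,
    kb: KnowledgeBase,
    lex: LexicalRelations,
    backend: SimilarityBackend | str = SimilarityBackend.STRING,
    embeddings: EmbeddingTable | None = None,
    cfg: FilterConfig | None = None,
    stopwords: frozenset[str] | None = None,
    keywords: dict[str, list[str]] | None = None,
    no_answer_line: str = NO_ANSWER_LINE,
    **scoring_kwargs,
) -> Answer:
    """Full QA pipeline: parse, score, gate, type-filter, verbalize.

    Deterministic for fixed inputs and configuration; every failure mode
    degrades to an unanswered :class:`Answer`.
    """
    if isinstance(backend, str):
        backend = SimilarityBackend(backend)
    cfg = cfg or FilterConfig()
    parsed = parse_question(question, stopwords=stopwords, keywords=keywords)

    instance_triples = kb.object_assertions + kb.data_assertions
    scored = score_assertions(
        instance_triples, parsed, lex, backend, embeddings,
        stopwords=stopwords, **scoring_kwargs,
    )
    class_scored = score_assertions(
        kb.class_assertions, parsed, lex, backend, embeddings,
        stopwords=stopwords, **scoring_kwargs,
    )

    candidates = select_candidates(scored, cfg)
    if parsed.qtype in (
        QuestionType.COUNT, QuestionType.MAX, QuestionType.MIN, QuestionType.NUMERIC
    ):
        survivors = numeric_filter(candidates, cfg)
    else:
        survivors = class_assertion_filter(candidates, class_scored, kb, cfg)

    survivors = sorted(survivors, key=_sort_key)
    if cfg.max_triples > 0:
        survivors = survivors[: cfg.max_triples]
    selected = [ts.triple for ts in survivors]
    answered = bool(selected)
    text = render_answer(selected, no_answer_line) if answered else no_answer_line
    return Answer(
        selected=selected,
        text=text,
        answered=answered,
        qtype=parsed.qtype,
        scores=scored,
        class_scores=class_scored,
    )
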