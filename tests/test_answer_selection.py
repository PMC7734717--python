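"""Candidate gating, type-specific filters, verbalization, full pipeline."""

import math
import random

import pytest

from coofoqus.answer_selection import (
    NO_ANSWER_LINE,
    FilterConfig,
    answer_question,
    class_assertion_filter,
    numeric_filter,
    render_answer,
    select_candidates,
)
from coofoqus.fixtures import KBFixtureConfig, generate_toy_kb
from coofoqus.kb_model import AssertionKind, AssertionTriple, Entity, load_ontology
from coofoqus.question_analysis import QuestionType
from coofoqus.scoring import TripleScore


def _triple(i, kind=AssertionKind.OBJECT_PROPERTY, labels=None):
    d, p, r = labels or (f"subject {i}", f"property {i}", f"object {i}")
    rng = r if kind is AssertionKind.DATA_PROPERTY else Entity(f"urn:r{i}", r)
    return AssertionTriple(Entity(f"urn:d{i}", d), Entity(f"urn:p{i}", p), rng, kind)


def _scored(scores, kinds=None, labels=None):
    kinds = kinds or [AssertionKind.OBJECT_PROPERTY] * len(scores)
    out = []
    for i, (s, k) in enumerate(zip(scores, kinds)):
        lab = labels[i] if labels else None
        out.append(TripleScore(_triple(i, k, lab), None, s, s))
    return out


def test_top_gate_selects_top_fraction():
    """Top object score 0.55 with 10 triples -> the ceil(0.2*10)=2 best survive."""
    scores = [0.55, 0.30, 0.10, 0.52, 0.20, 0.05, 0.15, 0.25, 0.35, 0.40]
    out = select_candidates(_scored(scores), FilterConfig())
    assert sorted(ts.combined for ts in out) == [0.52, 0.55]


def test_fallback_threshold_branch():
    """Top object score below the gate -> keep everything above 45%."""
    out = select_candidates(_scored([0.48, 0.46, 0.30]), FilterConfig())
    assert sorted(ts.combined for ts in out) == [0.46, 0.48]
    assert select_candidates(_scored([0.0, 0.0]), FilterConfig()) == []


def test_gate_uses_object_scores_only():
    """A high-scoring data triple does not open the top-20% gate."""
    kinds = [AssertionKind.DATA_PROPERTY] + [AssertionKind.OBJECT_PROPERTY] * 2
    out = select_candidates(_scored([0.9, 0.47, 0.2], kinds), FilterConfig())
    assert sorted(ts.combined for ts in out) == [0.47, 0.9]  # fallback branch


def test_boundary_ties_included():
    scores = [0.8, 0.6, 0.6, 0.6, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1]
    out = select_candidates(_scored(scores), FilterConfig())
    assert sorted(ts.combined for ts in out) == [0.6, 0.6, 0.6, 0.8]


def _brute_force_filter(scored, cfg):
    objs = [ts.combined for ts in scored
            if ts.triple.kind is AssertionKind.OBJECT_PROPERTY]
    if objs and max(objs) > cfg.top_gate:
        ranked = sorted(scored, key=lambda ts: -ts.combined)
        k = math.ceil(cfg.top_fraction * len(ranked))
        cut = ranked[k - 1].combined
        return {id(ts) for ts in scored if ts.combined >= cut}
    return {id(ts) for ts in scored if ts.combined > cfg.fallback_threshold}


@pytest.mark.parametrize("n", [5, 10, 50])
def test_select_matches_brute_force_randomized(n):
    cfg = FilterConfig()
    rng = random.Random(1000 + n)
    for _ in range(200):
        scores = [round(rng.random(), 3) for _ in range(n)]
        kinds = [
            rng.choice([AssertionKind.OBJECT_PROPERTY, AssertionKind.DATA_PROPERTY])
            for _ in range(n)
        ]
        scored = _scored(scores, kinds)
        got = {id(ts) for ts in select_candidates(scored, cfg)}
        assert got == _brute_force_filter(scored, cfg)


def test_numeric_filter():
    labels = [
        ("vaccine", "requires", "one dose"),
        ("vaccine", "protects", "adults"),
        ("vaccine", "requires", "3 doses"),
    ]
    kinds = [AssertionKind.DATA_PROPERTY] * 3
    cands = _scored([0.9, 0.9, 0.9], kinds, labels)
    kept = numeric_filter(cands)
    assert [ts.triple.labels()[2] for ts in kept] == ["one dose", "3 doses"]
    # "one" must match as a whole word, not inside "bone"
    bone = _scored([0.9], [AssertionKind.DATA_PROPERTY], [("x", "y", "bone density")])
    assert numeric_filter(bone) == []


def test_class_assertion_filter_worked_example(toy_kb, lexicon):
    throat = next(
        t for t in toy_kb.object_assertions
        if t.labels() == ("throat cancer", "affects", "males")
    )
    disease_affects_people = next(
        t for t in toy_kb.class_assertions
        if t.labels() == ("disease", "affects", "people")
    )
    other_class = next(
        t for t in toy_kb.class_assertions
        if t.labels() == ("insurance plan", "covers", "vaccine")
    )
    cand = [TripleScore(throat, None, 0.9, 0.9)]
    in_t = [TripleScore(disease_affects_people, None, 0.8, 0.8)]
    out_t = [TripleScore(other_class, None, 0.8, 0.8),
             TripleScore(disease_affects_people, None, 0.0, 0.0)]
    assert class_assertion_filter(cand, in_t, toy_kb) == cand
    # the instantiated schema triple scored outside the top fraction -> dropped
    assert class_assertion_filter(cand, out_t, toy_kb, FilterConfig(top_fraction=0.5)) == []


def test_class_filter_empty_strict_vs_permissive(toy_kb):
    cand = _scored([0.9])
    assert class_assertion_filter(cand, [], toy_kb) == []
    permissive = FilterConfig(permissive_class_filter=True)
    assert class_assertion_filter(cand, [], toy_kb, permissive) == cand


def test_render_answer():
    throat = _triple(0, labels=("throat cancer", "affects", "males"))
    assert render_answer([throat]) == "Throat cancer affects males."
    assert render_answer([]) == NO_ANSWER_LINE
    second = _triple(1, labels=("cervical cancer", "affects", "females"))
    both = render_answer([throat, second])
    assert both == "Throat cancer affects males; also, cervical cancer affects females."


def test_answer_question_worked_example(toy_kb, lexicon, embeddings):
    answer = answer_question("how does hpv affect males", toy_kb, lexicon)
    assert answer.answered
    assert ("throat cancer", "affects", "males") in [t.labels() for t in answer.selected]
    assert answer.qtype is QuestionType.UNKNOWN


def test_answer_question_stages_only_remove(toy_kb, lexicon):
    answer = answer_question("how does hpv affect males", toy_kb, lexicon)
    universe = set(toy_kb.object_assertions + toy_kb.data_assertions)
    assert set(answer.selected) <= universe


def test_answer_question_count_path(toy_kb, lexicon):
    answer = answer_question("how many doses does the hpv vaccine require", toy_kb, lexicon)
    assert answer.answered and answer.qtype is QuestionType.COUNT
    assert ("hpv vaccine", "requires", "3 doses") in [t.labels() for t in answer.selected]


def test_answer_question_no_answer(toy_kb, lexicon):
    answer = answer_question("what is the weather like today", toy_kb, lexicon)
    assert not answer.answered
    assert answer.selected == []
    assert answer.text == NO_ANSWER_LINE


def test_empty_kb_always_unanswered(tmp_path, lexicon):
    path = generate_toy_kb(
        KBFixtureConfig(include_worked_example=False), tmp_path / "empty.ttl"
    )
    kb = load_ontology(path)
    for q in ["how does hpv affect males", "how many doses", "insurance"]:
        assert not answer_question(q, kb, lexicon).answered


def test_pipeline_deterministic(toy_kb, lexicon, embeddings):
    import json

    def snapshot(backend):
        a = answer_question("how does hpv affect males", toy_kb, lexicon,
                            backend, embeddings)
        return json.dumps(
            {"text": a.text, "selected": [t.labels() for t in a.selected],
             "scores": [round(ts.combined, 12) for ts in a.scores]},
            sort_keys=True,
        )

    for backend in ("string", "vector"):
        assert snapshot(backend) == snapshot(backend)


def test_filter_config_validation():
    with pytest.raises(ValueError):
        FilterConfig(top_gate=0.4, fallback_threshold=0.45)
    with pytest.raises(ValueError):
        FilterConfig(top_fraction=0.0)
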