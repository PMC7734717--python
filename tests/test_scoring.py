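"""Similarity backends, lexical adjustment, and triple-score assembly."""

import itertools
import random

import numpy as np
import pytest

from coofoqus.kb_model import AssertionKind, AssertionTriple, Entity
from coofoqus.question_analysis import parse_question
from coofoqus.scoring import (
    EmbeddingTable,
    LexicalRelations,
    SimilarityBackend,
    lexical_adjust,
    monge_elkan,
    score_triple,
    swg_similarity,
    vector_similarity,
)

MATCH, MISMATCH, GAP = 1.0, -1.0, -0.5


def nw_global(a: str, b: str) -> float:
    """Needleman-Wunsch global alignment with linear gaps (oracle helper)."""
    n, m = len(a), len(b)
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * GAP
    for j in range(1, m + 1):
        F[0][j] = j * GAP
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            F[i][j] = max(F[i - 1][j - 1] + sub, F[i - 1][j] + GAP, F[i][j - 1] + GAP)
    return F[n][m]


def local_alignment_oracle(a: str, b: str) -> float:
    """Best local score = max global score over all substring pairs."""
    best = 0.0
    for i1, j1 in itertools.combinations(range(len(a) + 1), 2):
        for i2, j2 in itertools.combinations(range(len(b) + 1), 2):
            best = max(best, nw_global(a[i1:j1], b[i2:j2]))
    if not a or not b:
        return 0.0
    return min(1.0, max(0.0, best / max(len(a), len(b))))


def all_strings(alphabet: str, max_len: int):
    for length in range(max_len + 1):
        yield from ("".join(p) for p in itertools.product(alphabet, repeat=length))


def test_swg_fixed_points():
    assert swg_similarity("vaccine", "vaccine") == 1.0
    assert swg_similarity("abc", "xyz") == 0.0
    assert swg_similarity("", "abc") == 0.0
    assert swg_similarity("abc", "") == 0.0


def test_swg_matches_alignment_oracle_exhaustive():
    for a in all_strings("abc", 3):
        for b in all_strings("abc", 3):
            if not a or not b:
                continue
            assert swg_similarity(a, b) == pytest.approx(local_alignment_oracle(a, b))


def test_swg_matches_alignment_oracle_sampled():
    rng = random.Random(20240)
    for _ in range(120):
        a = "".join(rng.choice("abc") for _ in range(rng.randint(1, 8)))
        b = "".join(rng.choice("abc") for _ in range(rng.randint(1, 8)))
        assert swg_similarity(a, b) == pytest.approx(local_alignment_oracle(a, b))


def test_monge_elkan_fixed_points():
    tokens = ["hpv", "vaccine"]
    assert monge_elkan(tokens, tokens) == pytest.approx(1.0)
    assert monge_elkan(["hpv"], ["hpv", "vaccine"]) == pytest.approx(1.0)
    assert monge_elkan([], ["x"]) == 0.0
    assert monge_elkan(["x"], []) == 0.0


def test_monge_elkan_matches_double_loop():
    rng = random.Random(7)
    vocab = ["alpha", "beta", "gamma", "delta", "hpv", "dose"]
    for _ in range(50):
        ta = [rng.choice(vocab) for _ in range(rng.randint(1, 4))]
        tb = [rng.choice(vocab) for _ in range(rng.randint(1, 4))]
        expected = np.mean(
            [max(swg_similarity(x, y) for y in tb) for x in ta]
        )
        assert monge_elkan(ta, tb) == pytest.approx(min(1.0, expected))


def test_vector_similarity():
    emb = EmbeddingTable({"x": [1.0, 0.0], "y": [0.0, 1.0], "z": [1.0, 1.0]})
    assert vector_similarity(["x"], ["x"], emb) == pytest.approx(1.0)
    assert vector_similarity(["x"], ["y"], emb) == pytest.approx(0.0)
    # mean([x, y]) = (0.5, 0.5); cosine with z = 1
    assert vector_similarity(["x", "y"], ["z"], emb) == pytest.approx(1.0)
    assert vector_similarity(["x", "y"], ["x"], emb) == pytest.approx(np.cos(np.pi / 4))
    assert vector_similarity(["oov"], ["x"], emb) == 0.0
    with pytest.raises(ValueError):
        EmbeddingTable({"x": [1.0], "y": [1.0, 2.0]})


def test_lexical_adjust_branches():
    lex = LexicalRelations([("affect", "syn", "impact", 1),
                            ("cancer", "hypo", "disease", 2)])
    assert lexical_adjust(0.6, ["affect"], ["impact"], lex) == pytest.approx(0.75)
    assert lexical_adjust(0.6, ["affect"], ["weather"], lex) == 0.0
    assert lexical_adjust(0.6, ["cancer"], ["disease"], lex) == pytest.approx(0.6)
    # boost is capped at 1
    assert lexical_adjust(0.9, ["affect"], ["impact"], lex) == 1.0
    # identical terms count as synonymous (shared synset)
    assert lexical_adjust(0.8, ["males"], ["males"], lex) == 1.0
    # depth bound: synonymy deeper than the bound is still a relation
    deep = LexicalRelations([("a", "syn", "b", 5)])
    assert lexical_adjust(0.6, ["a"], ["b"], deep, synonym_depth=3) == pytest.approx(0.6)


def test_lexical_adjust_monotone_per_branch():
    lex = LexicalRelations([("a", "syn", "b", 1), ("c", "hyper", "d", 1)])
    grid = np.linspace(0, 1, 21)
    for branch_terms in ((["a"], ["b"]), (["c"], ["d"]), (["x"], ["y"])):
        vals = [lexical_adjust(s, *branch_terms, lex) for s in grid]
        assert all(v2 >= v1 for v1, v2 in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)


def _triple(dom, prop, rng):
    return AssertionTriple(
        Entity(f"urn:{dom}", dom.replace("_", " ")),
        Entity(f"urn:{prop}", prop.replace("_", " ")),
        Entity(f"urn:{rng}", rng.replace("_", " ")),
        AssertionKind.OBJECT_PROPERTY,
    )


def test_score_triple_worked_example(lexicon):
    q = parse_question("how does hpv affect males")
    ts = score_triple(_triple("throat_cancer", "affects", "males"), q, lexicon)
    assert ts.predicate_score == pytest.approx(1.0)  # affect ~ affects after lemma
    assert ts.entity_score == pytest.approx(1.0)  # males matches exactly
    assert ts.combined > 0.5


def test_score_triple_no_verb_phrase(lexicon):
    q = parse_question("hpv males")
    assert q.verb_phrases == []
    ts = score_triple(_triple("throat_cancer", "affects", "males"), q, lexicon)
    assert ts.predicate_score is None
    assert ts.combined == ts.entity_score


def test_score_triple_disjoint_vocabulary(lexicon):
    q = parse_question("how does weather change sleep")
    ts = score_triple(_triple("throat_cancer", "affects", "males"), q, lexicon)
    assert ts.combined == 0.0


def test_scores_stay_in_unit_interval(lexicon, embeddings):
    questions = ["how does hpv affect males", "doses", "weather", "hpv vaccine dose"]
    triples = [
        _triple("throat_cancer", "affects", "males"),
        _triple("hpv_vaccine", "prevents", "hpv"),
        _triple("insurance_plan", "covers", "hpv_vaccine"),
    ]
    for text in questions:
        q = parse_question(text)
        for t in triples:
            for backend in (SimilarityBackend.STRING, SimilarityBackend.VECTOR):
                ts = score_triple(t, q, lexicon, backend, embeddings)
                assert 0.0 <= ts.entity_score <= 1.0
                assert 0.0 <= ts.combined <= 1.0
                if ts.predicate_score is not None:
                    assert 0.0 <= ts.predicate_score <= 1.0
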