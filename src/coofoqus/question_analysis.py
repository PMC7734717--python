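"""Question parsing: phrase chunking, term cleaning, question typing.

A user question is reduced to cleaned noun-phrase and verb-phrase term
lists plus a six-way type (UNKNOWN / ALL / COUNT / MAX / MIN / NUMERIC)
driven by a keyword table. Cleaning lowercases, strips special
characters (underscores included), de-duplicates, drops words on a
100-entry common-word list, and normalizes each word to its root with a
rule-based lemmatizer (plural -> singular, inflected verb -> base).

Chunking is intentionally lightweight: tokens are tagged as function
words, verbs (closed lexicon of common and domain verbs plus their
inflections) or nouns, and maximal runs of same-tag content tokens form
the phrases. Transcribed speech is noisy, so the parser never raises on
arbitrary printable input; when no noun phrase can be chunked, all
content tokens fall back to a single noun phrase.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "QuestionType",
    "ParsedQuestion",
    "classify_question_type",
    "extract_phrases",
    "clean_terms",
    "lemmatize",
    "parse_question",
    "load_stopwords",
]


class QuestionType(enum.Enum):
    UNKNOWN = "UNKNOWN"
    ALL = "ALL"
    COUNT = "COUNT"
    MAX = "MAX"
    MIN = "MIN"
    NUMERIC = "NUMERIC"


#: keyword precedence when several rules fire
_TYPE_PRECEDENCE = ("COUNT", "MAX", "MIN", "NUMERIC", "ALL")

_DEFAULT_KEYWORDS = {
    "COUNT": ["how many", "the number of"],
    "MAX": ["most", "maximum", "highest", "largest"],
    "MIN": ["least", "minimum", "lowest", "smallest"],
    "NUMERIC": ["how much", "how old", "what age", "what number"],
    "ALL": ["list all", "what are all", "give me all"],
}


@dataclass
class ParsedQuestion:
    raw: str
    noun_phrases: list[list[str]] = field(default_factory=list)
    verb_phrases: list[list[str]] = field(default_factory=list)
    qtype: QuestionType = QuestionType.UNKNOWN


def load_stopwords(path: str | Path | None = None) -> frozenset[str]:
    """Common-word list; the packaged 100-entry file unless overridden."""
    if path is None:
        text = resources.files("coofoqus.data").joinpath("common_words.txt").read_text("utf-8")
    else:
        text = Path(path).read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines() if w.strip())


_STOPWORDS_CACHE: frozenset[str] | None = None


def _default_stopwords() -> frozenset[str]:
    global _STOPWORDS_CACHE
    if _STOPWORDS_CACHE is None:
        _STOPWORDS_CACHE = load_stopwords()
    return _STOPWORDS_CACHE


# ---------------------------------------------------------------- lemmatizer

_LEMMA_EXCEPTIONS = {
    "men": "man", "women": "woman", "children": "child", "feet": "foot",
    "teeth": "tooth", "mice": "mouse", "people": "people", "viruses": "virus",
    "does": "do", "has": "have", "had": "have", "was": "be", "were": "be",
    "is": "be", "are": "be", "said": "say", "made": "make", "given": "give",
    "taken": "take", "told": "tell", "got": "get", "gotten": "get",
    "needed": "need", "needing": "need",
    "covered": "cover", "covering": "cover",
    "required": "require", "requiring": "require",
    "caused": "cause", "causing": "cause",
    "used": "use", "using": "use",
    "received": "receive", "receiving": "receive",
    "vaccinated": "vaccinate", "vaccinating": "vaccinate",
}

_VOWELS = "aeiou"


def lemmatize(word: str) -> str:
    """Map an inflected form to its root with suffix rules + exceptions.

    Handles the behaviors the pipeline relies on: plural -> singular and
    3rd-person/participle verb forms -> base. Unknown or already-base
    words pass through unchanged.
    """
    w = word.lower()
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if len(w) <= 3:
        return w
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith(("ches", "shes", "xes", "zes")):
        return w[:-2]
    if w.endswith("ses") and len(w) > 4:
        return w[:-1]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    for suffix in ("ing", "ed"):
        if w.endswith(suffix) and len(w) - len(suffix) >= 3:
            stem = w[: -len(suffix)]
            if not any(c in _VOWELS for c in stem):
                break
            if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in "lsz":
                stem = stem[:-1]
            elif stem.endswith(("v", "c", "z", "u")):
                stem = stem + "e"
            return stem
    return w


# ----------------------------------------------------------------- cleaning

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def _tokenize(text: str) -> list[str]:
    return [t for t in _NON_ALNUM.split(text.lower()) if t]


def clean_terms(phrase: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercase, strip special characters, de-duplicate, de-stop, lemmatize.

    The stop filter runs both before and after lemmatization so the
    output is a fixed point: cleaning the joined output again returns
    the same list.
    """
    if stopwords is None:
        stopwords = _default_stopwords()
    seen: set[str] = set()
    out: list[str] = []
    for tok in _tokenize(phrase):
        if tok in stopwords:
            continue
        root = lemmatize(tok)
        if root in stopwords or root in seen:
            continue
        seen.add(root)
        out.append(root)
    return out


# ----------------------------------------------------------------- chunking

_FUNCTION_WORDS = frozenset("""
a an the this that these those some any each every either neither
i you he she it we they me him her us them my your his its our their
who whom whose what which when where why how
am is are was were be been being do does did have has had
can could will would shall should may might must
of in on at by for with about against between into through during
before after above below to from up down out off over under again
further then once here there and or but if because as until while
not no nor only so than too very just
""".split())

_VERB_BASES = [
    "tell", "say", "ask", "answer", "cover", "affect", "cause", "prevent",
    "protect", "require", "need", "cost", "get", "give", "take", "make",
    "know", "think", "want", "recommend", "vaccinate", "receive", "help",
    "occur", "happen", "spread", "infect", "transmit", "develop", "reduce",
    "increase", "cure", "treat", "catch",
]


def _inflections(base: str) -> set[str]:
    forms = {base}
    forms.add(base + "s" if not base.endswith(("s", "ch", "sh", "x", "z")) else base + "es")
    if base.endswith("e"):
        forms.add(base[:-1] + "ing")
        forms.add(base + "d")
    else:
        forms.add(base + "ing")
        forms.add(base + "ed")
    return forms


_VERB_FORMS = frozenset(
    f for b in _VERB_BASES for f in _inflections(b)
) | {"told", "said", "gave", "took", "got", "gotten", "knew", "thought", "made", "caught"}


def extract_phrases(text: str) -> tuple[list[str], list[str]]:
    """Chunk a question into noun-phrase and verb-phrase strings.

    Maximal runs of noun-tagged tokens form noun phrases (multiword
    phrases stay intact, e.g. "hpv vaccine"); verb-tagged runs form verb
    phrases. Function words separate chunks and are dropped. If chunking
    yields no noun phrase, all content tokens become one noun phrase so
    the question stays processable.
    """
    tokens = _tokenize(text)
    noun_phrases: list[str] = []
    verb_phrases: list[str] = []
    run: list[str] = []
    run_tag: str | None = None

    def flush() -> None:
        nonlocal run, run_tag
        if run:
            (noun_phrases if run_tag == "N" else verb_phrases).append(" ".join(run))
        run, run_tag = [], None

    for tok in tokens:
        if tok in _FUNCTION_WORDS:
            flush()
            continue
        tag = "V" if tok in _VERB_FORMS else "N"
        if tag != run_tag:
            flush()
            run_tag = tag
        run.append(tok)
    flush()

    if not noun_phrases:
        content = [t for t in tokens if t not in _FUNCTION_WORDS]
        if content:
            noun_phrases = [" ".join(content)]
    return noun_phrases, verb_phrases


# -------------------------------------------------------------- typing

def classify_question_type(
    text: str, keywords: dict[str, list[str]] | None = None
) -> QuestionType:
    """Keyword-rule question typing; UNKNOWN when no rule fires.

    Single-word keywords match on word boundaries (so "most" does not
    fire inside "almost"); multiword keywords match as phrases.
    """
    if keywords is None:
        keywords = _DEFAULT_KEYWORDS
    lowered = " ".join(_tokenize(text))
    for qtype in _TYPE_PRECEDENCE:
        for kw in keywords.get(qtype, ()):
            if re.search(r"\b" + re.escape(kw.lower()) + r"\b", lowered):
                return QuestionType[qtype]
    return QuestionType.UNKNOWN


def parse_question(
    text: str,
    stopwords: frozenset[str] | None = None,
    keywords: dict[str, list[str]] | None = None,
) -> ParsedQuestion:
    """Full Step-2 analysis: type, chunked phrases, cleaned terms."""
    nps, vps = extract_phrases(text)
    noun_terms = [t for t in (clean_terms(p, stopwords) for p in nps) if t]
    verb_terms = [t for t in (clean_terms(p, stopwords) for p in vps) if t]
    return ParsedQuestion(
        raw=text,
        noun_phrases=noun_terms,
        verb_phrases=verb_terms,
        qtype=classify_question_type(text, keywords),
    )
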