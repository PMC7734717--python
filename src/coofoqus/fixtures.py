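"""Deterministic fixture generators: dialogue ontology, toy vaccine KB,
similarity resources, and the scripted user sessions.

``generate_dialogue_ontology`` emits a counseling-script ontology whose
replica preset contains exactly 19 utterance individuals linked by
``precedes``: a full health-topic block (health information, a confirm
prompt, and confirmation / disconfirmation / repeat / question branches
with their question-answering sub-flow) followed by a reduced follow-up
topic and a closing. ``generate_toy_kb`` emits a small vaccine knowledge
base carrying the worked-example triple throat_cancer -> affects ->
males together with its schema support (Disease -> affects -> People and
the chain Males < People_of_Gender < People), plus insurance-coverage
and dose-count assertions so both question-answering entry paths and the
COUNT path are exercisable.

Everything is generated from code; identical configurations produce
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .scoring import EmbeddingTable, LexicalRelations

__all__ = [
    "DialogueFixtureConfig",
    "KBFixtureConfig",
    "DIALOGUE_NS",
    "KB_NS",
    "replica_config",
    "generate_dialogue_ontology",
    "generate_toy_kb",
    "toy_embedding_vectors",
    "toy_embeddings",
    "toy_lexicon_entries",
    "toy_lexicon",
    "write_embedding_table",
    "write_lexical_table",
    "scripted_sessions",
    "write_fixture_set",
]

DIALOGUE_NS = "http://example.org/phido#"
KB_NS = "http://example.org/viso#"

FULL_BRANCHES = ("confirm", "disconfirm", "repeat", "question")


@dataclass
class DialogueFixtureConfig:
    n_topics: int = 2
    branches: tuple[str, ...] = FULL_BRANCHES
    tail_branches: tuple[str, ...] = ("confirm", "disconfirm", "repeat")
    closing: bool = True
    seed: int = 0
    namespace: str = DIALOGUE_NS
    first_id: int = 776  # numbering of utterance individuals

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if "confirm" not in self.branches or "confirm" not in self.tail_branches:
            raise ValueError("the confirm branch is mandatory")
        if not self.namespace.endswith(("#", "/")):
            raise ValueError(f"namespace must end in '#' or '/': {self.namespace}")


@dataclass
class KBFixtureConfig:
    n_diseases: int = 0
    n_properties: int = 0
    seed: int = 0
    include_worked_example: bool = True
    namespace: str = KB_NS


def replica_config() -> DialogueFixtureConfig:
    """The 19-instance counseling-script preset used throughout the tests."""
    return DialogueFixtureConfig()


# --------------------------------------------------------------- dialogue

_TOPIC_TEXTS = [
    "The HPV vaccine is available to you whether or not you have insurance.",
    "Some people believe the HPV vaccine causes long-term health problems, "
    "but studies show it is safe.",
]

_CONFIRM_EXAMPLES = ["yes", "yeah", "ok", "i understand", "got it"]
_DISCONFIRM_EXAMPLES = ["not really", "no", "i don't think so", "nah"]
_REPEAT_EXAMPLES = ["can you repeat that", "say that again", "repeat please"]
_QUESTION_EXAMPLES = ["can you tell me something", "i have a question",
                      "i have another question", "one more question"]
_NO_QUESTION_EXAMPLES = ["nah", "no", "nope no question", "no questions"]
_NO_MORE_EXAMPLES = ["nope no question", "no", "no thanks", "that is all"]

_CONFIRM_PROMPT = "You following me so far?"
_ASK_QUESTION_TEXT = "Hmm. Is there a question I can answer for you?"
_QA_FOLLOWUP_TEXT = "Do you have any other questions?"
_REFERRAL_TEXT = ("If you still have concerns, it is best to ask your health "
                  "care provider. Let's move on.")
_CLOSING_TEXT = "Thanks for talking with me about the HPV vaccine today."


@dataclass
class _Node:
    name: str
    cls: str
    text: str = ""
    examples: list[str] = field(default_factory=list)
    succ: list[str] = field(default_factory=list)


def _topic_text(i: int) -> str:
    if i <= len(_TOPIC_TEXTS):
        return _TOPIC_TEXTS[i - 1]
    return f"Here is health fact number {i} about the HPV vaccine."


def build_dialogue_graph(cfg: DialogueFixtureConfig) -> dict[str, _Node]:
    """The utterance graph as named nodes; the serializer renders it."""
    nodes: dict[str, _Node] = {}
    counter = cfg.first_id

    def add(stem: str, cls: str, text: str = "", examples: list[str] | None = None) -> str:
        nonlocal counter
        name = f"utterance_{stem}_{counter}"
        counter += 1
        nodes[name] = _Node(name, cls, text, list(examples or []))
        return name

    topic_entries: list[str] = []
    blocks: list[dict[str, str]] = []
    for i in range(1, cfg.n_topics + 1):
        tail = i == cfg.n_topics
        branches = cfg.tail_branches if tail else cfg.branches
        blk: dict[str, str] = {"tail": "yes" if tail else ""}
        blk["hi"] = add("health_info", "Health_Information", _topic_text(i))
        blk["chi"] = add("health_info", "Confirm_Health_Information", _CONFIRM_PROMPT)
        if "repeat" in branches:
            blk["rep"] = add("RSR", "Request_System_Repeat", examples=_REPEAT_EXAMPLES)
        blk["conf"] = add("confirmation", "Confirmation_Utterance",
                          examples=_CONFIRM_EXAMPLES)
        if "disconfirm" in branches:
            blk["disc"] = add("disconfirmation", "Disconfirmation_Utterance",
                              examples=_DISCONFIRM_EXAMPLES)
        if not tail and "question" in branches:
            blk["q"] = add("question", "Question_Utterance", examples=_QUESTION_EXAMPLES)
            blk["qaf"] = add("question_followup", "Question_Followup_Prompt",
                             _QA_FOLLOWUP_TEXT)
            blk["qmore"] = add("question", "Question_Utterance",
                               examples=_QUESTION_EXAMPLES)
            blk["nomore"] = add("no_more_questions", "Disconfirmation_Utterance",
                                examples=_NO_MORE_EXAMPLES)
        if not tail and "disconfirm" in branches:
            blk["askq"] = add("ask_question", "Ask_For_Question", _ASK_QUESTION_TEXT)
            if "question" in branches:
                blk["qd"] = add("question", "Question_Utterance",
                                examples=_QUESTION_EXAMPLES)
            blk["noq"] = add("no_question", "Disconfirmation_Utterance",
                             examples=_NO_QUESTION_EXAMPLES)
            blk["ref"] = add("provider_referral", "Provider_Referral", _REFERRAL_TEXT)
        topic_entries.append(blk["hi"])
        blocks.append(blk)

    exit_node = add("closing", "Closing_Utterance", _CLOSING_TEXT) if cfg.closing else None

    for i, blk in enumerate(blocks):
        nxt = topic_entries[i + 1] if i + 1 < len(topic_entries) else exit_node
        link = lambda a, b: b is not None and nodes[a].succ.append(b)  # noqa: E731
        link(blk["hi"], blk["chi"])
        for key in ("conf", "disc", "rep", "q"):
            if key in blk:
                nodes[blk["chi"]].succ.append(blk[key])
        link(blk["conf"], nxt)
        if "rep" in blk:
            link(blk["rep"], blk["hi"])
        if blk["tail"]:
            if "disc" in blk:
                link(blk["disc"], nxt)
            continue
        if "disc" in blk:
            link(blk["disc"], blk["askq"])
            if "qd" in blk:
                link(blk["askq"], blk["qd"])
                link(blk["qd"], blk["qaf"])
            link(blk["askq"], blk["noq"])
            link(blk["noq"], blk["ref"])
            link(blk["ref"], nxt)
        if "q" in blk:
            link(blk["q"], blk["qaf"])
            link(blk["qaf"], blk["qmore"])
            link(blk["qaf"], blk["nomore"])
            link(blk["qmore"], blk["qaf"])
            link(blk["nomore"], nxt)
    return nodes


_DIALOGUE_CLASSES = {
    "Health_Information": "System_Utterance",
    "Confirm_Health_Information": "System_Utterance",
    "Question_Followup_Prompt": "System_Utterance",
    "Ask_For_Question": "System_Utterance",
    "Provider_Referral": "System_Utterance",
    "Closing_Utterance": "System_Utterance",
    "Confirmation_Utterance": "Participant_Utterance",
    "Disconfirmation_Utterance": "Participant_Utterance",
    "Question_Utterance": "Participant_Utterance",
    "Request_System_Repeat": "Participant_Utterance",
}


def _ttl_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def generate_dialogue_ontology(cfg: DialogueFixtureConfig, out_path: str | Path) -> Path:
    """Serialize the dialogue fixture as Turtle. Returns the written path.

    All ``hasFocus`` flags are serialized false; the engine sets the
    focus at initialization.
    """
    nodes = build_dialogue_graph(cfg)
    ns = cfg.namespace
    lines = [
        f"@prefix : <{ns}> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
        ":Utterance a owl:Class .",
        ":System_Utterance a owl:Class ; rdfs:subClassOf :Utterance .",
        ":Participant_Utterance a owl:Class ; rdfs:subClassOf :Utterance .",
    ]
    for cls, parent in _DIALOGUE_CLASSES.items():
        lines.append(f":{cls} a owl:Class ; rdfs:subClassOf :{parent} .")
    lines += [
        "",
        ":precedes a owl:ObjectProperty .",
        ":hasFocus a owl:DatatypeProperty .",
        ":hasUtteranceText a owl:DatatypeProperty .",
        ":hasUtteranceExample a owl:DatatypeProperty .",
        "",
    ]
    for name, node in nodes.items():
        parts = [f":{name} a :{node.cls}", '    :hasFocus "false"^^xsd:boolean']
        if node.text:
            parts.append(f'    :hasUtteranceText "{_ttl_escape(node.text)}"')
        for ex in node.examples:
            parts.append(f'    :hasUtteranceExample "{_ttl_escape(ex)}"')
        for succ in node.succ:
            parts.append(f"    :precedes :{succ}")
        lines.append(" ;\n".join(parts) + " .")
        lines.append("")
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines), encoding="utf-8")
    return out_path


# ---------------------------------------------------------------- toy KB

_KB_CLASS_HIERARCHY = [
    ("Cancer", "Disease"),
    ("Throat_Cancer", "Cancer"),
    ("Cervical_Cancer", "Cancer"),
    ("People_of_Gender", "People"),
    ("Males", "People_of_Gender"),
    ("Females", "People_of_Gender"),
]
_KB_ROOT_CLASSES = ["Disease", "People", "Virus", "Vaccine", "Insurance_Plan", "Dosage"]
_KB_OBJECT_PROPS = ["affects", "causes", "prevents", "covers", "related_to"]
_KB_DATA_PROPS = ["requires", "recommended_for_age", "has_code"]

_KB_CLASS_ASSERTIONS = [
    ("Disease", "affects", "People"),
    ("Virus", "causes", "Disease"),
    ("Vaccine", "prevents", "Virus"),
    ("Insurance_Plan", "covers", "Vaccine"),
    ("Vaccine", "requires", "Dosage"),
]

_KB_INDIVIDUALS = [
    ("throat_cancer", "Throat_Cancer"),
    ("cervical_cancer", "Cervical_Cancer"),
    ("males", "Males"),
    ("females", "Females"),
    ("hpv", "Virus"),
    ("hpv_vaccine", "Vaccine"),
    ("insurance_plan", "Insurance_Plan"),
]

_KB_OBJECT_ASSERTIONS = [
    ("throat_cancer", "affects", "males"),
    ("cervical_cancer", "affects", "females"),
    ("hpv", "causes", "throat_cancer"),
    ("hpv", "causes", "cervical_cancer"),
    ("hpv_vaccine", "prevents", "hpv"),
    ("insurance_plan", "covers", "hpv_vaccine"),
]

_KB_DATA_ASSERTIONS = [
    ("hpv_vaccine", "requires", "3 doses"),
    ("hpv_vaccine", "recommended_for_age", "ages 11 to 12"),
]


def generate_toy_kb(cfg: KBFixtureConfig, out_path: str | Path) -> Path:
    """Serialize the toy vaccine knowledge base as Turtle.

    ``n_diseases`` appends seeded synthetic disease individuals (each
    with an ``affects`` link and a code literal) to scale the assertion
    lists; ``n_properties`` adds extra object properties cycled over
    those synthetics.
    """
    ns = cfg.namespace
    lines = [
        f"@prefix : <{ns}> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "",
    ]
    for cls in _KB_ROOT_CLASSES:
        lines.append(f":{cls} a owl:Class .")
    for sub, sup in _KB_CLASS_HIERARCHY:
        lines.append(f":{sub} a owl:Class ; rdfs:subClassOf :{sup} .")
    lines.append("")
    extra_props = [f"related_to_{j}" for j in range(cfg.n_properties)]
    for prop in _KB_OBJECT_PROPS + extra_props:
        lines.append(f":{prop} a owl:ObjectProperty .")
    for prop in _KB_DATA_PROPS:
        lines.append(f":{prop} a owl:DatatypeProperty .")
    lines.append("")
    for dom, prop, rng in _KB_CLASS_ASSERTIONS:
        lines.append(f":{dom} :{prop} :{rng} .")
    lines.append("")

    if cfg.include_worked_example:
        for ind, cls in _KB_INDIVIDUALS:
            lines.append(f":{ind} a :{cls} .")
        lines.append("")
        for s, p, o in _KB_OBJECT_ASSERTIONS:
            lines.append(f":{s} :{p} :{o} .")
        for s, p, lit in _KB_DATA_ASSERTIONS:
            lines.append(f':{s} :{p} "{_ttl_escape(lit)}" .')
        lines.append("")

    rng_state = np.random.RandomState(cfg.seed)
    for i in range(cfg.n_diseases):
        name = f"synthetic_disease_{i:03d}"
        target = "males" if rng_state.random_sample() < 0.5 else "females"
        lines.append(f":{name} a :Disease .")
        if cfg.include_worked_example:
            lines.append(f":{name} :affects :{target} .")
            if extra_props:
                lines.append(f":{name} :{extra_props[i % len(extra_props)]} :hpv .")
        lines.append(f':{name} :has_code "D{i:03d}" .')
    out_path = Path(out_path)
    out_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return out_path


# --------------------------------------------------- similarity resources

def toy_embedding_vectors() -> dict[str, list[float]]:
    """Hand-authored 16-dimensional vectors over the fixture vocabulary.

    Terms are keyed by lemma; related concepts share a dominant
    dimension so that within-group cosines are high and cross-group
    cosines are near zero.
    """
    d = 16
    sparse = {
        "hpv": {0: 1.0, 5: 0.3},
        "virus": {0: 1.0},
        "vaccine": {1: 1.0, 0: 0.2},
        "vaccination": {1: 0.95, 0: 0.2, 15: 0.1},
        "dose": {2: 1.0, 1: 0.3},
        "dosage": {2: 0.95, 1: 0.3},
        "insurance": {3: 1.0},
        "plan": {3: 0.85, 15: 0.2},
        "people": {4: 1.0},
        "person": {4: 0.97},
        "gender": {4: 0.8, 7: 0.3},
        "male": {4: 0.75, 7: 0.6},
        "female": {4: 0.75, 7: -0.6},
        "disease": {5: 1.0, 0: 0.2},
        "cancer": {5: 0.95, 6: 0.2},
        "throat": {6: 1.0, 4: 0.1},
        "cervical": {6: 0.95, 5: 0.2},
        "affect": {8: 1.0},
        "cause": {9: 1.0, 8: 0.3},
        "cover": {10: 1.0},
        "prevent": {11: 1.0, 10: 0.2},
        "require": {12: 1.0},
        "need": {12: 0.9, 15: 0.1},
        "tell": {13: 1.0},
        "ask": {13: 0.9},
        "age": {14: 1.0},
        "old": {14: 0.85},
        "3": {2: 0.8, 15: 0.3},
        "11": {14: 0.5, 15: 0.4},
        "12": {14: 0.5, 15: 0.45},
    }
    out: dict[str, list[float]] = {}
    for term, entries in sparse.items():
        vec = [0.0] * d
        for idx, val in entries.items():
            vec[idx] = val
        out[term] = vec
    return out


def toy_embeddings() -> EmbeddingTable:
    return EmbeddingTable(toy_embedding_vectors())


def toy_lexicon_entries() -> list[tuple[str, str, str, int]]:
    """Hand-written WordNet-style relation table for the fixture domain."""
    return [
        ("person", "syn", "people", 1),
        ("male", "hypo", "person", 2),
        ("male", "hypo", "people", 2),
        ("female", "hypo", "person", 2),
        ("female", "hypo", "people", 2),
        ("cancer", "hypo", "disease", 2),
        ("hpv", "hypo", "virus", 2),
        ("vaccination", "syn", "vaccine", 1),
        ("dosage", "syn", "dose", 1),
        ("need", "syn", "require", 2),
        ("cover", "syn", "coverage", 1),
        ("age", "syn", "old", 2),
    ]


def toy_lexicon() -> LexicalRelations:
    return LexicalRelations(toy_lexicon_entries())


def write_embedding_table(out_path: str | Path) -> Path:
    out_path = Path(out_path)
    rows = [
        term + " " + " ".join(f"{v:g}" for v in vec)
        for term, vec in toy_embedding_vectors().items()
    ]
    out_path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return out_path


def write_lexical_table(out_path: str | Path) -> Path:
    out_path = Path(out_path)
    rows = ["\t".join((t1, rel, t2, str(depth)))
            for t1, rel, t2, depth in toy_lexicon_entries()]
    out_path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return out_path


# ------------------------------------------------------------- sessions

INSURANCE_QUESTION = "can you tell me if insurance covers the hpv vaccine"
INSURANCE_PLANS_QUESTION = "can you tell me if insurance plans cover vaccination"
AFFECT_MALES_QUESTION = "how does hpv affect males"
UNANSWERABLE_QUESTION = "what is the weather like today"
COUNT_QUESTION = "how many doses does the hpv vaccine require"


def scripted_sessions(cfg: DialogueFixtureConfig | None = None) -> dict[str, dict]:
    """The nine named user sessions for the replica fixture.

    Each session carries the ordered user inputs, the questions it
    routes to the QA subsystem, and the expected focus trace (utterance
    local names, in visit order, ending at the follow-up topic's confirm
    prompt where the script runs out).
    """
    cfg = cfg or replica_config()
    nodes = build_dialogue_graph(cfg)
    names = list(nodes)

    def pick(stem_cls: tuple[str, str], k: int = 0) -> str:
        matches = [n for n in names
                   if n.startswith(f"utterance_{stem_cls[0]}_")
                   and nodes[n].cls == stem_cls[1]]
        return matches[k]

    hi1 = pick(("health_info", "Health_Information"), 0)
    chi1 = pick(("health_info", "Confirm_Health_Information"), 0)
    rep1 = pick(("RSR", "Request_System_Repeat"), 0)
    conf1 = pick(("confirmation", "Confirmation_Utterance"), 0)
    disc1 = pick(("disconfirmation", "Disconfirmation_Utterance"), 0)
    q1 = pick(("question", "Question_Utterance"), 0)
    qaf1 = pick(("question_followup", "Question_Followup_Prompt"), 0)
    qmore1 = pick(("question", "Question_Utterance"), 1)
    nomore1 = pick(("no_more_questions", "Disconfirmation_Utterance"), 0)
    askq1 = pick(("ask_question", "Ask_For_Question"), 0)
    qd1 = pick(("question", "Question_Utterance"), 2)
    noq1 = pick(("no_question", "Disconfirmation_Utterance"), 0)
    ref1 = pick(("provider_referral", "Provider_Referral"), 0)
    hi2 = pick(("health_info", "Health_Information"), 1)
    chi2 = pick(("health_info", "Confirm_Health_Information"), 1)

    return {
        "confirm": {
            "inputs": ["yes"],
            "questions": [],
            "expected_focus": [hi1, chi1, conf1, hi2, chi2],
        },
        "disconfirm-no-question": {
            "inputs": ["not really", "nah"],
            "questions": [],
            "expected_focus": [hi1, chi1, disc1, askq1, noq1, ref1, hi2, chi2],
        },
        "repeat": {
            "inputs": ["can you repeat that", "yes"],
            "questions": [],
            "expected_focus": [hi1, chi1, rep1, hi1, chi1, conf1, hi2, chi2],
        },
        "unintelligible": {
            "inputs": ["blorp fizzle wug", "snarfle gronk"],
            "questions": [],
            "expected_focus": [hi1, chi1, hi2, chi2],
        },
        "qa-via-disconfirm": {
            "inputs": ["not really", INSURANCE_QUESTION, "nope no question"],
            "questions": [INSURANCE_QUESTION],
            "expected_focus": [hi1, chi1, disc1, askq1, qd1, qaf1, nomore1, hi2, chi2],
        },
        "qa-via-direct-question": {
            "inputs": [INSURANCE_QUESTION, "no"],
            "questions": [INSURANCE_QUESTION],
            "expected_focus": [hi1, chi1, q1, qaf1, nomore1, hi2, chi2],
        },
        "question-answered": {
            "inputs": ["does insurance cover the hpv vaccine", "no thanks"],
            "questions": ["does insurance cover the hpv vaccine"],
            "expected_focus": [hi1, chi1, q1, qaf1, nomore1, hi2, chi2],
        },
        "question-unanswered": {
            "inputs": ["not really", UNANSWERABLE_QUESTION, "nope no question"],
            "questions": [UNANSWERABLE_QUESTION],
            "expected_focus": [hi1, chi1, disc1, askq1, qd1, qaf1, nomore1, hi2, chi2],
        },
        "multi-question": {
            "inputs": [INSURANCE_PLANS_QUESTION, AFFECT_MALES_QUESTION,
                       "nope no question"],
            "questions": [INSURANCE_PLANS_QUESTION, AFFECT_MALES_QUESTION],
            "expected_focus": [hi1, chi1, q1, qaf1, qmore1, qaf1, nomore1, hi2, chi2],
        },
    }


def write_fixture_set(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write every fixture artifact (ontologies, tables, session scripts)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = replica_config()
    cfg.seed = seed
    paths = {
        "dialogue": generate_dialogue_ontology(cfg, out_dir / "dialogue.ttl"),
        "kb": generate_toy_kb(KBFixtureConfig(seed=seed), out_dir / "toy_kb.ttl"),
        "embeddings": write_embedding_table(out_dir / "embeddings.txt"),
        "lexicon": write_lexical_table(out_dir / "lexicon.tsv"),
    }
    scripts_dir = out_dir / "sessions"
    scripts_dir.mkdir(exist_ok=True)
    for name, session in scripted_sessions(cfg).items():
        path = scripts_dir / f"{name}.txt"
        path.write_text("\n".join(session["inputs"]) + "\n", encoding="utf-8")
        paths[f"session:{name}"] = path
    return paths
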