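"""The conversational loop over an utterance ontology.

The dialogue model is a graph of utterance individuals linked by a
``precedes`` object property, with a single boolean ``hasFocus`` flag
marking where the conversation stands. System utterances carry the text
the agent speaks; participant utterances carry example strings of what
the user is expected to say, and the engine classifies transcribed user
input against those examples by token-level string similarity. A
participant branch typed as a Question utterance hands the raw user
string to a question-answering callback and speaks its answer (or an
apology) before moving on.

The loop: speak the focused system utterance, advance the focus along
``precedes``; at a participant branch point, obtain input, classify it,
advance to the matched branch. Exactly one node holds focus after every
transition.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Iterator

from .config import DEFAULTS, cfg_get
from .kb_model import Entity, KnowledgeBase, infer_classes, local_name
from .scoring import monge_elkan, swg_similarity

log = logging.getLogger(__name__)

__all__ = [
    "ParticipantCategory",
    "UtteranceNode",
    "DialogueState",
    "StepResult",
    "DialogueEngine",
    "initialize",
    "successors",
    "advance",
    "classify_user_utterance",
]


class ParticipantCategory(enum.Enum):
    CONFIRMATION = "CONFIRMATION"
    DISCONFIRMATION = "DISCONFIRMATION"
    QUESTION = "QUESTION"
    REQUEST_SYSTEM_REPEAT = "REQUEST_SYSTEM_REPEAT"
    UNINTELLIGIBLE = "UNINTELLIGIBLE"


class StepResult(enum.Enum):
    CONTINUE = "continue"
    COMPLETE = "complete"
    TRUNCATED = "truncated"


@dataclass
class UtteranceNode:
    entity: Entity
    text: str
    focus: bool = False
    examples: list[str] = field(default_factory=list)
    classes: frozenset[str] = frozenset()  # local names of derived classes
    category: str = "SYSTEM"  # "SYSTEM" | "PARTICIPANT"
    participant_category: ParticipantCategory | None = None

    @property
    def iri(self) -> str:
        return self.entity.iri


@dataclass
class DialogueState:
    nodes: dict[str, UtteranceNode]
    precedence: dict[str, list[str]]
    transcript: list[dict] = field(default_factory=list)
    focus_trace: list[str] = field(default_factory=list)

    @property
    def focused(self) -> UtteranceNode | None:
        flagged = [n for n in self.nodes.values() if n.focus]
        if len(flagged) > 1:  # pragma: no cover - invariant guard
            raise RuntimeError("single-focus invariant violated")
        return flagged[0] if flagged else None

    def say(self, speaker: str, text: str, node_iri: str | None = None,
            category: str | None = None) -> None:
        self.transcript.append(
            {"speaker": speaker, "text": text, "node_iri": node_iri, "category": category}
        )


def _tokens(text: str) -> list[str]:
    return [t for t in "".join(
        c if c.isalnum() else " " for c in text.lower()
    ).split() if t]


def _build_nodes(kb: KnowledgeBase, vocab: dict) -> tuple[dict[str, UtteranceNode], dict[str, list[str]]]:
    utterance_cls = vocab["utterance_class"]
    system_cls = vocab["system_class"]
    participant_cls = vocab["participant_class"]
    category_map = vocab["participant_categories"]

    nodes: dict[str, UtteranceNode] = {}
    for iri in kb.individuals():
        try:
            classes = {local_name(e.iri) for e in infer_classes(kb, iri)}
        except KeyError:
            continue
        if utterance_cls not in classes:
            continue
        is_system = system_cls in classes
        is_participant = participant_cls in classes
        if is_system == is_participant:
            raise ValueError(
                f"utterance {iri} must be exactly one of System/Participant"
            )
        participant_category = None
        if is_participant:
            matched = sorted(c for c in classes if c in category_map)
            participant_category = (
                ParticipantCategory[category_map[matched[0]]] if matched else None
            )
        texts = kb.data_values(iri, vocab["has_text"])
        focus_vals = kb.data_values(iri, vocab["has_focus"])
        nodes[iri] = UtteranceNode(
            entity=kb.entity(iri),
            text=texts[0] if texts else "",
            focus=any(v.lower() == "true" for v in focus_vals),
            examples=kb.data_values(iri, vocab["has_example"]),
            classes=frozenset(classes),
            category="PARTICIPANT" if is_participant else "SYSTEM",
            participant_category=participant_category,
        )

    precedence = {
        iri: [t for t in kb.object_values(iri, vocab["precedes"]) if t in nodes]
        for iri in nodes
    }
    return nodes, precedence


def initialize(kb: KnowledgeBase, start: Entity | str, vocab: dict | None = None) -> DialogueState:
    """Build a dialogue state from an utterance ontology and focus ``start``."""
    vocab = vocab or DEFAULTS["vocab"]
    nodes, precedence = _build_nodes(kb, vocab)
    start_iri = start.iri if isinstance(start, Entity) else start
    if start_iri not in nodes:
        raise ValueError(f"start node is not an utterance individual: {start_iri}")
    for node in nodes.values():
        node.focus = False
    nodes[start_iri].focus = True
    state = DialogueState(nodes=nodes, precedence=precedence)
    state.focus_trace.append(start_iri)
    return state


def successors(state: DialogueState, node: UtteranceNode) -> list[UtteranceNode]:
    """Outgoing ``precedes`` targets in deterministic (IRI-sorted) order."""
    if node.iri not in state.nodes:
        raise ValueError(f"node not in dialogue graph: {node.iri}")
    return [state.nodes[iri] for iri in sorted(state.precedence.get(node.iri, []))]


def advance(state: DialogueState, next_node: UtteranceNode) -> DialogueState:
    """Move the focus flag to ``next_node``, preserving single focus."""
    if next_node.iri not in state.nodes:
        raise ValueError(f"cannot advance to unknown node: {next_node.iri}")
    current = state.focused
    if current is not None:
        current.focus = False
    state.nodes[next_node.iri].focus = True
    state.focus_trace.append(next_node.iri)
    return state


def _default_similarity(text: str, example: str) -> float:
    return monge_elkan(_tokens(text), _tokens(example), swg_similarity)


def classify_user_utterance(
    text: str,
    candidates: list[UtteranceNode],
    threshold: float = 0.5,
    interrogative_keywords: Iterable[str] | None = None,
    similarity: Callable[[str, str], float] | None = None,
) -> tuple[UtteranceNode | None, ParticipantCategory]:
    """Match user input to a participant branch, or fall back.

    Each candidate scores the maximum token-level similarity of the
    input against its example strings. The best candidate wins when it
    reaches the threshold (ties break toward the lowest IRI, with a
    logged warning). Below threshold, an interrogative cue (leading
    question word or trailing question mark) routes to a Question branch
    when one exists — transcribed questions rarely resemble canned
    examples. Otherwise the input is unintelligible.
    """
    if not text or not candidates:
        return None, ParticipantCategory.UNINTELLIGIBLE
    sim = similarity or _default_similarity
    scored = sorted(
        ((max((sim(text, ex) for ex in c.examples), default=0.0), c.iri, c)
         for c in candidates),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, _, best = scored[0]
    if len(scored) > 1 and scored[1][0] == best_score and best_score >= threshold:
        log.warning("classification tie at %.3f; choosing lowest IRI %s", best_score, best.iri)
    if best_score >= threshold:
        return best, best.participant_category or ParticipantCategory.UNINTELLIGIBLE

    keywords = set(
        interrogative_keywords
        if interrogative_keywords is not None
        else cfg_get(DEFAULTS, "dialogue.interrogative_keywords")
    )
    toks = _tokens(text)
    is_question = text.strip().endswith("?") or (toks and toks[0] in keywords)
    if is_question:
        questions = sorted(
            (c for c in candidates
             if c.participant_category is ParticipantCategory.QUESTION),
            key=lambda c: c.iri,
        )
        if questions:
            return questions[0], ParticipantCategory.QUESTION
    return None, ParticipantCategory.UNINTELLIGIBLE


class DialogueEngine:
    """Drives the utterance graph: speak, listen, classify, advance.

    ``qa_callback`` takes the raw question string and returns either an
    object with ``answered``/``text`` attributes, a plain string, or
    None (no answer).
    """

    def __init__(self, kb: KnowledgeBase, config: dict | None = None):
        self.kb = kb
        self.config = config or DEFAULTS
        self.vocab = self.config["vocab"]
        dlg = self.config["dialogue"]
        self.threshold = dlg["match_threshold"]
        self.max_unintelligible = dlg["max_unintelligible"]
        self.interrogatives = dlg["interrogative_keywords"]
        self.lines = dlg["lines"]

    def initialize(self, start: Entity | str) -> DialogueState:
        return initialize(self.kb, start, self.vocab)

    # -- helpers -----------------------------------------------------------

    def _continue_target(self, candidates: list[UtteranceNode],
                         state: DialogueState) -> UtteranceNode | None:
        """Where the dialogue resumes after giving up on classification:
        the confirmation branch's successor, else the first branch's."""
        ordered = sorted(candidates, key=lambda c: c.iri)
        preferred = [
            c for c in ordered
            if c.participant_category is ParticipantCategory.CONFIRMATION
        ] or ordered
        for cand in preferred:
            nxt = successors(state, cand)
            if nxt:
                return nxt[0]
        return None

    def _answer(self, state: DialogueState, question: str, qa_callback) -> None:
        answer = qa_callback(question) if qa_callback is not None else None
        if answer is None:
            text, answered = self.lines["no_answer"], False
        elif isinstance(answer, str):
            text, answered = answer, True
        else:
            answered = bool(getattr(answer, "answered", True))
            text = answer.text if answered else self.lines["no_answer"]
        state.say("agent", text, category="ANSWER" if answered else "NO_ANSWER")

    # -- the loop ----------------------------------------------------------

    def step(
        self,
        state: DialogueState,
        user_input_provider: Callable[[], str | None] | Iterator[str],
        qa_callback=None,
    ) -> StepResult:
        """One exchange: speak the focused utterance and advance the focus.

        A system node with participant successors consumes user inputs
        until one classifies (unintelligible inputs first draw a
        clarification, then a segue to the continue path).
        """
        if not callable(user_input_provider):
            it = iter(user_input_provider)
            user_input_provider = lambda: next(it, None)  # noqa: E731

        node = state.focused
        if node is None:
            raise RuntimeError("dialogue not initialized")

        if node.category == "PARTICIPANT":
            nxt = successors(state, node)
            if not nxt:
                return StepResult.COMPLETE
            if len(nxt) > 1:
                raise ValueError(f"participant node {node.iri} must have one successor")
            advance(state, nxt[0])
            return StepResult.CONTINUE

        # SYSTEM node: speak it
        state.say("agent", node.text, node_iri=node.iri, category="SYSTEM")
        succ = successors(state, node)
        if not succ:
            return StepResult.COMPLETE
        participants = [n for n in succ if n.category == "PARTICIPANT"]
        if not participants:
            if len(succ) > 1:
                raise ValueError(
                    f"system node {node.iri} has multiple system successors"
                )
            advance(state, succ[0])
            return StepResult.CONTINUE

        unintelligible = 0
        while True:
            text = user_input_provider()
            if text is None:
                state.say("system", "[dialogue truncated: awaiting user input]",
                          node_iri=node.iri, category="TRUNCATED")
                return StepResult.TRUNCATED
            matched, category = classify_user_utterance(
                text, participants, self.threshold, self.interrogatives
            )
            state.say("user", text, node_iri=matched.iri if matched else None,
                      category=category.value)
            if category is ParticipantCategory.UNINTELLIGIBLE:
                unintelligible += 1
                if unintelligible >= self.max_unintelligible:
                    state.say("agent", self.lines["segue"], category="SEGUE")
                    target = self._continue_target(participants, state)
                    if target is None:
                        return StepResult.COMPLETE
                    advance(state, target)
                    return StepResult.CONTINUE
                state.say("agent", self.lines["clarification"], category="CLARIFICATION")
                continue
            if category is ParticipantCategory.QUESTION:
                self._answer(state, text, qa_callback)
            advance(state, matched)
            return StepResult.CONTINUE

    def run(
        self,
        state: DialogueState,
        scripted_inputs: Iterable[str],
        qa_callback=None,
        max_steps: int = 1000,
    ) -> list[dict]:
        """Step until the dialogue completes or the script runs out."""
        it = iter(scripted_inputs)
        provider = lambda: next(it, None)  # noqa: E731
        for _ in range(max_steps):
            result = self.step(state, provider, qa_callback)
            if result is not StepResult.CONTINUE:
                break
        return state.transcript
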