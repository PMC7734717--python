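"""Default configuration and YAML overlay loading.

Every tunable named by the other modules bottoms out here so that the
CLI, the test fixtures and library callers share one source of defaults.
Dotted-path access (``cfg_get(cfg, "scoring.swg.match")``) is used
throughout.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

DEFAULTS: dict[str, Any] = {
    "vocab": {
        # local names of the dialogue-ontology vocabulary
        "precedes": "precedes",
        "has_focus": "hasFocus",
        "has_text": "hasUtteranceText",
        "has_example": "hasUtteranceExample",
        "utterance_class": "Utterance",
        "system_class": "System_Utterance",
        "participant_class": "Participant_Utterance",
        "participant_categories": {
            "Confirmation_Utterance": "CONFIRMATION",
            "Disconfirmation_Utterance": "DISCONFIRMATION",
            "Question_Utterance": "QUESTION",
            "Request_System_Repeat": "REQUEST_SYSTEM_REPEAT",
        },
    },
    "dialogue": {
        "match_threshold": 0.5,
        "max_unintelligible": 2,
        "interrogative_keywords": [
            "who", "what", "when", "where", "why", "how",
            "can", "could", "does", "do", "is", "are", "will", "would", "should",
        ],
        "lines": {
            "clarification": "Sorry, I didn't quite catch that. Could you say that again?",
            "segue": "I may have misunderstood you. Let's move on to the next topic.",
            "no_answer": "I'm sorry, I don't have an answer for that one. "
                         "It is best to ask your health care provider.",
        },
    },
    "question_types": {
        # keyword table; precedence is the listed order
        "keywords": {
            "COUNT": ["how many", "the number of"],
            "MAX": ["most", "maximum", "highest", "largest"],
            "MIN": ["least", "minimum", "lowest", "smallest"],
            "NUMERIC": ["how much", "how old", "what age", "what number"],
            "ALL": ["list all", "what are all", "give me all"],
        },
    },
    "stopwords": {"path": None},  # None -> packaged common-word list
    "scoring": {
        "backend": "string",  # "string" | "vector"
        "swg": {"match": 1.0, "mismatch": -1.0, "gap": -0.5},
        "boost": 1.25,
        "synonym_depth": 3,
        "entity_aggregation": "max",  # "max" | "mean"
    },
    "filter": {
        "top_gate": 0.50,
        "top_fraction": 0.20,
        "fallback_threshold": 0.45,
    },
    "class_filter": {"permissive": False},
    "answer": {
        "max_triples": 3,
        "number_words": ["one", "two", "three", "four", "five",
                         "six", "seven", "eight", "nine", "ten"],
    },
}


def _merge(base: dict, overlay: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in overlay.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, deep-merged with an optional YAML file and a dict overlay."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            file_cfg = yaml.safe_load(fh) or {}
        if not isinstance(file_cfg, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _merge(cfg, file_cfg)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def cfg_get(cfg: dict, dotted: str) -> Any:
    node: Any = cfg
    for part in dotted.split("."):
        node = node[part]
    return node
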