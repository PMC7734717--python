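# coo-foqus

Ontology-driven dialogue management and ontology question answering for
consumer-health counseling agents, in pure Python.

The package implements two cooperating engines:

* **COO** (`coofoqus.dialogue_engine`) — a deterministic, plan-based
  dialogue manager. The counseling script lives in an ontology: utterance
  individuals are linked by a `precedes` object property, a single boolean
  `hasFocus` data property marks where the conversation stands, and
  participant utterances carry `hasUtteranceExample` strings of what the
  user is expected to say. The engine speaks the focused system utterance,
  classifies transcribed user input against the example strings by
  token-level string similarity, advances the focus along `precedes`, and
  hands questions to the QA subsystem.
* **FOQUS** (`coofoqus.answer_selection` and friends) — question answering
  over an OWL knowledge base. Object-property, data-property and
  class-level assertions are mined as candidate triples
  (domain → property → range); the question is chunked into noun and verb
  phrases, cleaned, and typed; each triple is scored; and the best
  candidates are filtered and verbalized.

## The scoring and filtering model

For a triple *t* = (d, p, r) and a parsed question with verb phrases
*V* and noun phrases *N*, the per-triple score is

    pred(t) = max_{v ∈ V}  adjust(sim(terms(p), v))        (absent if V = ∅)
    ent(t)  = max_{e ∈ {d,r}, n ∈ N}  adjust(sim(terms(e), n))
    score(t) = mean(pred(t), ent(t))                        (ent alone if V = ∅)

where `sim` is either Monge-Elkan over cleaned tokens with a normalized
Smith-Waterman-Gotoh local character alignment as the inner metric
(*string* backend), or the cosine of mean word vectors (*vector*
backend). `adjust` is a WordNet-style lexical rule: a synonymous term
pair within graph depth 3 boosts the score by 25% (capped at 1), the
absence of any synonym/hypernym/hyponym relation zeroes it, and any
other relation leaves it unchanged.

Selection then applies a rank gate — if the best object-property score
exceeds 50%, keep the top 20% of the object+data triples, otherwise keep
everything above 45% — followed by a numeric-content filter for
COUNT/MAX/MIN questions, or, for other question types, a schema
cross-check that keeps a candidate only when one of the class assertions
it instantiates (via the subclass closure of its members' types) scores
in the top 20% of the class assertions.

## Worked example

Generate the bundled fixtures (a 19-instance counseling-script ontology,
a toy vaccine knowledge base, an embedding table, a lexical-relation
table, and nine scripted user sessions), then run a counseling session
in which the user asks a question:

```sh
coo fixtures --out fixtures/
coo run --dialogue fixtures/dialogue.ttl --kb fixtures/toy_kb.ttl \
    --lexicon fixtures/lexicon.tsv \
    --script fixtures/sessions/qa-via-direct-question.txt
```

prints:

```
agent: The HPV vaccine is available to you whether or not you have insurance.
agent: You following me so far?
user: can you tell me if insurance covers the hpv vaccine
agent: Insurance plan covers hpv vaccine.
agent: Do you have any other questions?
user: no
agent: Some people believe the HPV vaccine causes long-term health problems, but studies show it is safe.
agent: You following me so far?
system: [dialogue truncated: awaiting user input]
```

The agent imparts the first health fact, recognizes the user's reply as
a Question utterance, routes it to the QA subsystem (which retrieves the
`insurance_plan → covers → hpv_vaccine` assertion and verbalizes it),
offers a follow-up, and segues to the next health topic; the final line
marks the end of the scripted input.

A single question can also be asked directly:

```sh
foqus ask --kb fixtures/toy_kb.ttl --lexicon fixtures/lexicon.tsv \
    --question "how does hpv affect males"
# -> Throat cancer affects males; also, cervical cancer affects females.
```

Here the instance triple `throat_cancer → affects → males` survives the
schema cross-check because it instantiates `Disease → affects → People`
(throat_cancer is typed Throat_Cancer ⊑ Cancer ⊑ Disease; males is typed
Males ⊑ People_of_Gender ⊑ People), which is the top-scoring class
assertion for this question.

## Layout

```
src/coofoqus/
  kb_model.py          ontology loading, assertion mining, subclass closure
  dialogue_engine.py   the COO loop: focus traversal, classification, QA handoff
  question_analysis.py chunking, term cleaning, question typing
  scoring.py           SWG / Monge-Elkan / cosine backends, lexical adjustment
  answer_selection.py  gating, numeric and schema filters, verbalization
  fixtures.py          deterministic fixture and session generators
  cli.py               `coo` and `foqus` entry points
docs/methods.md        model, parameters, numerical choices, limitations
```
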