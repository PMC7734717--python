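# Methods

## Dialogue model

The dialogue is a directed graph of utterance individuals in an
ontology. System utterances (machine turns) carry the spoken text in a
`hasUtteranceText` data property; participant utterances (human turns)
carry `hasUtteranceExample` strings. `precedes` links an utterance to
its possible successors; branching occurs only at participant turns —
a system utterance with more than one system successor is rejected as a
fixture error. A boolean `hasFocus` marks the single utterance where the
conversation stands; the engine maintains the invariant that exactly one
node holds focus after every transition. Whether an individual is a
system or participant utterance is derived structurally: asserted types
plus the transitive subclass closure, which is sufficient for every
behavior the fixture ontologies exercise. Full description-logic
reasoning (disjointness, property chains, cardinality) is deliberately
out of scope: the structural closure is deterministic, dependency-light,
and exact on acyclic named-class hierarchies.

### User-utterance classification

At a participant branch point, every candidate branch scores the maximum
Monge-Elkan similarity (Smith-Waterman-Gotoh inner metric, raw lowercase
tokens — the stop-list is not applied here, because replies such as
"no" or "not really" are made of stop words) of the user input against
its example strings. The best candidate wins when it reaches the match
threshold (default 0.5, configurable); ties break toward the lowest IRI
with a logged warning. Below threshold, an interrogative cue — a leading
question word (who/what/when/where/why/how/can/could/does/do/is/are/
will/would/should) or a trailing question mark — routes the input to a
Question branch when one is offered. The cue is deliberately subordinate
to similarity matching: transcribed questions rarely resemble canned
examples (so the cue is needed to capture them), but many non-question
branches also begin with auxiliaries ("can you repeat that"), so an
above-threshold example match must win first. Input matching nothing,
with no cue, is Unintelligible: the first such input draws a
clarification re-prompt; after `max_unintelligible` consecutive failures
(default 2) the agent speaks a segue line and resumes at the
confirmation branch's continuation target, i.e. the next health topic.

A branch classified as a Question hands the raw input string to the QA
callback; the agent speaks the returned answer, or a fixed
apology-and-referral line when the callback reports no answer, then
proceeds to the question branch's successor (a follow-up prompt offering
another question). All engine-injected lines (clarification, segue,
no-answer) are configuration strings, not ontology nodes.

## Question analysis

Questions are typed by a keyword table with precedence
COUNT > MAX > MIN > NUMERIC > ALL > UNKNOWN. COUNT fires on "how many" /
"the number of"; the remaining keyword sets (MAX: most/maximum/highest/
largest; MIN: least/minimum/lowest/smallest; NUMERIC: how much/how old/
what age/what number; ALL: list all/what are all/give me all) are this
package's own table, config-overridable. Single-word keywords match on
word boundaries so "most" does not fire inside "almost".

Phrase extraction is a rule-based chunker: tokens are tagged as function
words (closed list of determiners, pronouns, auxiliaries, prepositions,
conjunctions, interrogatives), verbs (closed lexicon of common and
domain verbs with their inflections), or nouns (everything else);
maximal same-tag runs of content tokens form the phrases, so multiword
noun phrases like "hpv vaccine" stay intact. When chunking yields no
noun phrase, all content tokens fall back to one noun phrase — the
pipeline must degrade, never fail, on mis-transcribed speech.

Term cleaning lowercases, strips special characters (underscores
included), de-duplicates, removes words on a shipped 100-entry
common-word list, and normalizes each word to its root with a rule-based
lemmatizer (suffix rules plus a small exception table; plural → singular
and inflected verb → base are the pinned behaviors). The stop filter is
applied again after lemmatization so that cleaning is a fixed point:
re-cleaning the joined output returns the same terms.

## Triple scoring

Each candidate triple is rendered to labels (explicit `rdfs:label`, else
the IRI local name with underscores → spaces, lowercased). Because
ontology labels are content terms by construction, a label whose cleaned
form is emptied by the stop list (e.g. the class "People" — "people" is
on the common-word list) falls back to its lemmatized raw tokens rather
than an empty comparison.

The string backend is Monge-Elkan over cleaned tokens: the mean, over
the triple-label tokens, of each token's best inner similarity among the
phrase tokens. The inner metric is a normalized Smith-Waterman-Gotoh
local character alignment with match +1, mismatch −1 and gap −0.5, gap
open equal to gap extend (so the affine recurrence collapses to the
single-matrix form), normalized by the longer string's self-alignment
score and clamped to [0, 1]. These alignment parameters are pinned in
configuration; any consistent parameterization fits the method, and
pinning makes tests exact. The vector backend is the cosine of mean word
vectors from a pluggable embedding table (text format, one term per
line); out-of-vocabulary terms are skipped and an empty side scores 0.
The test fixtures ship a hand-authored 16-dimensional table over the
fixture vocabulary; production use can point at any pre-trained table of
the same file format.

Both backends' scores pass through a lexical-relation adjustment backed
by a pluggable relation table (`term1<TAB>relation<TAB>term2<TAB>depth`,
relations syn/hyper/hypo): a synonymous cross-pair within graph depth 3
multiplies the score by 1.25 (capped at 1); no relation of any kind
zeroes it; any other relation leaves it unchanged. Two identical terms
count as synonymous at depth 0 — a word shares a synset with itself —
otherwise exact matches would be zeroed whenever the table lacks a
reflexive entry. The adjustment is applied to each label/phrase
comparison independently (predicate and entity comparisons separately),
and entity comparisons aggregate by max (config-switchable to mean) so
the best-matching entity dominates. When the question has no verb
phrase, the predicate comparison is skipped entirely and the combined
score is the entity score; otherwise it is the mean of the two.

## Answer selection

Over the scored object+data triples with N members: if the best
object-property score exceeds `top_gate` (0.50), the top
⌈`top_fraction`·N⌉ (0.20) by rank are kept, with boundary ties all
included (the rank reading of "top 20%", and tie inclusion avoids
arbitrary drops); otherwise all triples above `fallback_threshold`
(0.45) are kept, with no further trimming. COUNT, MAX, MIN — and, by
this package's choice, NUMERIC — questions then keep only candidates
whose labels contain a digit or a number word ("one" … "ten",
config-extendable), matched as whole tokens. MAX/MIN do not additionally
compare magnitudes; the numeric-content filter is the extent of their
special handling. All other question types pass through the schema
cross-check: the top ⌈0.2·M⌉ of the M scored class assertions form the
admissible set, and a candidate survives iff one of the class assertions
it instantiates — domain's inferred classes × same property (or a
declared superproperty) × range's inferred classes — is admissible. With
zero class assertions the strict default drops every candidate (the
no-answer path); a `class_filter.permissive` flag passes all instead.
Data-property triples have a literal range that instantiates no class,
so they can only be selected through the numeric path — a consequence of
the schema check being meaningful only for instance-to-instance links.

At most `answer.max_triples` (3) survivors are verbalized, in score
order, as "<domain> <property> <range>" clauses joined by "; also, ",
sentence-cased and terminated with a period. An empty survivor set
yields an explicit no-answer marker, which the dialogue engine turns
into the apology-and-referral line.

## Fixtures

The replica dialogue fixture realizes one full health-topic block
(health information; confirm prompt; confirmation, disconfirmation,
repeat and question branches; the ask-a-question and provider-referral
sub-flow; the any-other-questions loop), a reduced follow-up topic
(confirm/disconfirm/repeat), and a closing — exactly 19 utterance
individuals, with all focus flags serialized false. The two pinned topic
texts are paraphrases of insurance availability and the long-term-effects
misbelief; sessions' transcripts are therefore byte-reproducible. The
exact per-class breakdown of the 19 instances is this package's own
topology (only the total and the branch structure are externally
constrained). Nine scripted sessions cover confirmation,
disconfirmation without a question, repeat, unintelligible input, both
question-answering entry paths, answered and unanswered questions, and
two sequential questions; every participant branch up to the scripted
horizon (the follow-up topic's confirm prompt, where each session ends)
is visited by at least one session. The follow-up topic's own branches
are structurally identical to the first topic's and lie beyond that
horizon by design.

The toy vaccine KB holds 6 object assertions, 2 data assertions
(dose-count and recommended-age literals, both with numeric content),
5 class assertions, and the subclass chains Throat_Cancer ⊑ Cancer ⊑
Disease and Males ⊑ People_of_Gender ⊑ People, so the schema cross-check,
the numeric path, and the no-answer path are all exercisable at desk
scale. `n_diseases`/`n_properties` append seeded synthetic individuals
to scale the assertion lists. What the fixtures do **not** emulate:
speech-recognition noise beyond fixed mis-transcription-style inputs,
vocabulary at the scale of a real vaccine ontology, lexical coverage
beyond the hand-written relation table, and real distributional
embeddings — passing tests demonstrate the mechanics of the method, not
retrieval quality on a production knowledge base.

## Numerical and testing choices

All similarity scores are clamped to [0, 1]; Monge-Elkan is asymmetric
by definition (triple-label tokens first) and tests assert the
definition, not symmetry. Determinism is enforced everywhere: successor
lists and candidate orderings are IRI-sorted, filter ties break on IRIs,
fixture serialization is hand-ordered text, and all sampled checks are
seeded. The alignment primitive is verified against an independent
oracle — the maximum, over all substring pairs, of a Needleman-Wunsch
global alignment — exhaustively for short strings (lengths ≤ 3–4 over a
three-letter alphabet) and on seeded random samples up to length 8;
Monge-Elkan is verified against direct enumeration exhaustively for
small token lists and on seeded samples of lists up to size 4 over a
six-token vocabulary; the filter cascade is verified against a
brute-force filter on 600 seeded random score sets (n ∈ {5, 10, 50}).
Exhaustive enumeration at the full sampled sizes would cost ~10^8 oracle
alignments, so the split into small-exhaustive plus seeded-sampled
coverage is the package's chosen problem size.

## Known limitations

* No description-logic reasoning; ontologies relying on inferred types
  beyond the subclass closure will under-report class memberships.
* The chunker's verb lexicon is closed; unlisted verbs are treated as
  nouns (harmless for entity matching, but the predicate comparison is
  then driven by a noun phrase instead).
* MAX/MIN questions filter for numeric content but do not rank by value.
* Multi-hop answers (joining two triples) and follow-up-question
  resolution are out of scope.
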