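# Methods

This note documents the models and procedures implemented in `chatkg`, the
parameters that matter, the synthetic-data generator's assumptions, and the
design choices made where the design was genuinely open.

## Graph model and identity

A knowledge graph is a typed directed multigraph stored as (head, relation,
tail) triples over entities with surface forms, attributes and alias sets.
Two normalization layers define identity everywhere:

* **surfaces** — case-fold, collapse internal whitespace, strip outer
  punctuation. Entity ids *are* normalized surfaces, so id-identity and
  surface-identity cannot drift apart, and a serialized graph re-reads to the
  same ids.
* **labels** — additionally separator-insensitive: `TreatedByMedication`,
  `treated_by_medication` and `treated by medication` are one label. This
  bridges the CamelCase typed relation schema and the snake_case completion
  option list without a hand-maintained mapping for the common case.

Triple identity is the normalized (head surface, relation, tail surface)
tuple; adding a batch twice is a no-op. Entity and relation type names live
in separate namespaces (the reference cardiology schema itself uses `Cause`
as both).

Per-type statistics count a triple once for every *distinct* entity type
among its two endpoints. This convention is embedded in the stats output
itself, because per-type triple tallies are meaningless without it and
plausible alternatives (head-type only, double-count) exist.

## Chunking

Documents are split greedily toward `max_words` (default 700), backtracking
to the best available boundary whose prefix already holds `min_words`
(default 500). Boundary quality is ranked paragraph break > sentence
terminator (`.`/`!`/`?` + whitespace) > line break; a single sentence longer
than `max_words` becomes its own oversized chunk rather than being cut
internally. Words are whitespace tokens — the 500–700 targets are word
counts, and token-exact model-budget enforcement is explicitly out of scope.
Chunking is deterministic and partition-exact: concatenating the chunks
reproduces the document up to whitespace at boundaries (property-tested over
randomized paragraph structures).

## The gateway and the scripted backend

All model access flows through prompt templates (`{{slot}}` substitution,
strict by default) and chat sessions whose full history is re-sent on every
call. Re-sending explicitly, rather than trusting server-side session state,
is what makes the two-step conditioning reproducible across backends.
Temperature defaults to 0: extraction is an annotation task, and any
nonzero temperature only adds variance to a task with a right answer.

The scripted backend is a lookup table keyed by (template id, canonicalized
key-slot values, chunk id). Templates declare which slots are *key slots*:
long free-text slots — the chunk text, the serialized triples in a
disambiguation prompt — are excluded, because a key containing them could
not be regenerated by an independent writer of the script. The chunk id
travels as session metadata, not prompt text. A missed lookup returns the
script's default response (default `"unknown"`), which every parser treats
conservatively: classification parses to false, relation prediction to the
empty label, link prediction to no answer, disambiguation to "distinct".
This single convention is what makes unscripted (hallucinated) content fail
closed throughout the pipeline.

A live chat-completion backend (stdlib HTTP, retry loop) implements the same
interface for real deployments; no test depends on it.

## Two-step extraction

Step 1 asks which of the schema's types (NER) or relations (RE) a chunk
contains; step 2 issues one query per confirmed type, riding on the session
so the text is not repeated. Consequences relied on elsewhere:

* call count is exactly `1 + #types present`, with step 2 skipped entirely
  on an empty step 1;
* errors are attributable: dropping a type in step 1 zeroes that type's
  recall and touches nothing else (tested);
* each answer is short and single-typed, which keeps parsing trivial.

The answer-format contract is line-oriented (`Type: e1; e2`, `(h, t)` pairs,
`(h, r, t)` triples, `None` for empty), with parsers tolerant of bullets and
numbering and of "No ..." phrasings as explicit empties. Conversational
models emit no formal grammar, so the parser accepts a small tolerant
language and records anything outside it as a parse failure rather than
guessing. Entities are phrase strings without character offsets — evaluation
is phrase-level and BIO tagging is deliberately not used.

Few-shot blocks are balanced: k/2 positive examples (chunks with items,
serialized in the answer format) and k/2 negative (chunks whose expected
answer is the explicit empty) — the null answer is a frequent real outcome
and the model must see it. Sampling is deterministic under a seed. Shot
blocks are embedded in step-1/vanilla prompts only; step-2 prompts stay
minimal.

## Disambiguation

Head entities are profiled by their outgoing triples. The default similarity
is Jaccard over (relation, tail) *pairs*; a "literal" mode computes the
four-way form |R_A∩R_B∩T_A∩T_B| / |R_A∪R_B∪T_A∪T_B| over the raw relation
and tail sets. The four-way intersection is empty whenever relation labels
and entity ids are disjoint vocabularies — i.e. on every ordinary graph — so
it cannot express "shared relations and tail entities"; the pair form is the
reading consistent with that intent, and the literal form is retained only
for fidelity experiments. Both-empty profiles score 0 by convention: absence
of evidence is not evidence of identity.

Candidates are all unordered head pairs scoring ≥ threshold (default 0.3 —
one shared pair out of three qualifies, the scale of typical alias overlap),
ranked by score with lexicographic tie-breaks. The model adjudicates each
pair from both entities' triples; an unparseable verdict is "distinct"
(a missed merge is recoverable, a wrong merge corrupts the graph). Merge
verdicts are closed transitively over connected components; the survivor
takes the decision's canonical surface (conflicts: the surface with most
triple support, logged), absorbs the other surfaces as aliases, and triples
are rewritten with duplicate and self-loop drops reported.

## Completion and cyclic verification

Candidate triples with one unknown field are resolved by the matching task
(relation prediction over a closed option list; link prediction phrased with
a type hint derived from the relation's schema signature). Fully specified
candidates then face up to four independent checks — classification,
relation prediction, tail-link, head-link — each casting a vote iff its
answer reproduces the candidate's corresponding field. The consensus policy
(`required_votes` over `applicable_checks`) decides acceptance; the default
is unanimity over {classify, relation, link_tail}, with the head-link check
optional. Unanimity maximizes precision of the accepted set, which is the
purpose of the mechanism: completion mines *new* assertions, so false
positives are the dominant risk. Acceptance is provably monotone in policy
strictness (tested over all 2⁴ check patterns).

Relation prediction answers must name a member of the option list: exact
normalized match first, else the longest option found inside the response,
else the empty label with a warning. Link-prediction answers are matched to
existing entities by normalized surface; unmatched answers auto-register
flagged `reviewed: false` when the relation's schema signature supplies an
entity type (mining new knowledge is the point), and are otherwise kept in
the ledger but not stored.

## Evaluation

Phrase-level scoring: an item matches gold only as a whole normalized
string — (surface, type) for NER, (head, relation, tail) for RE — per chunk,
summed. A chunk present on one side only contributes all-FP or all-FN. The
doubly vacuous case (no gold, no predictions anywhere) is defined as
P = R = F1 = 1 and flagged `vacuous`; one-sided emptiness scores 0.

Consensus gold is the 2-of-3 majority over three annotators; three-way
splits (impossible for binary labels) are returned as disputed. Cohen's
kappa is computed in closed form, (p_o − p_e)/(1 − p_e), with two constant
identical raters defined as κ = 1 (the chance-correction denominator
vanishes but agreement is perfect). Kappa is a two-rater statistic; a
three-expert panel is summarized by the three pairwise coefficients and
their unweighted mean, with the reduction named in the output.

## Synthetic fixtures

The generator emulates a disease-specific extraction corpus: a truth graph
drawn under the schema's endpoint constraints (every entity of every
relation-connected type participates in ≥ 1 triple; a type no relation can
touch — e.g. the reference schema's `Cause` entity type — is not
instantiated, since it could never be realized in text), one templated
sentence per triple packed into chunks of a configurable word range, gold
annotations aligned by construction, and a backend script answering every
prompt the pipeline will issue.

Error knobs and their rationale:

* `miss_rate` — each gold item independently omitted from scripted answers;
  a step-1 type is present iff one of its items survives. Item-level
  Bernoulli thinning makes measured recall binomial around 1 − miss, which
  is the calibration the degradation tests check.
* `halluc_rate` — spurious items with in-vocabulary types/relations and
  novel surfaces injected into answers and into the completion seed list.
  Hallucinated completion seeds get no script entries, so every check fails
  via the default response: the scripted model of an assertion the model
  cannot re-derive.
* `alias_rate` — a fraction of head entities (those with 2–5 outgoing
  triples) receive a duplicate surface; exactly two of their triples are
  re-realized under it, fixing the alias/canonical pair-Jaccard at
  2/k ∈ [0.4, 1], above the 0.3 candidate threshold, so alias recovery is a
  deterministic obligation rather than a coin flip.

Completion seeds are truth triples chosen greedily so that (h,r), (h,t) and
(r,t) projections are unique among the seeds — a single-answer link or
relation prompt is otherwise ambiguous and would fail a correct triple.

What the generator does **not** emulate: realistic clinical prose (one
template per relation), nested or discontinuous mentions, cross-sentence
coreference, annotator disagreement, and model answers outside the format
contract. Passing the closure test therefore certifies the *machinery* —
orchestration, parsing, merging, verification, scoring are lossless when the
model is perfect — and the degradation tests certify error accounting; they
say nothing about a live model's linguistic performance on real documents.

## Problem sizes and defaults

Fixture defaults (4 entities per connected type, 80 triples, 500–700-word
chunks) keep a full pipeline run under a second while exercising every code
path; the recall-calibration runs use 600 triples over 10 entities per type
so the binomial standard error at miss = 0.3 is ≈ 0.019 and a ±3σ band is
meaningfully tight. The similarity-oracle check sweeps 200 independent small
graphs. These sizes are the package's chosen study conditions and are
restated in `scripts/acceptance.py`, which recomputes all headline
quantities from scratch.

## Known limitations

* Disambiguation compares only head-entity profiles; entities appearing
  exclusively as tails are never nominated (an `incoming` profile extension
  is a natural follow-up).
* Triple identity ignores entity types, so two same-surface entities of
  different types would collide; with the shipped schema's disjoint surface
  vocabularies this does not arise, but a cross-disease deployment may need
  typed identity.
* The completion stage can only store triples whose relation carries a
  typed schema signature; accepted triples over vocabulary-only labels stay
  in the verification ledger.
* The live backend implements the plain chat-completion contract without
  streaming, cost accounting, or rate limiting.
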