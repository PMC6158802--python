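# Methods

This note documents the models, defaults, numerical choices and known
limitations behind `trkit`. It explains *why* the pipeline behaves the
way it does; the README shows *what* it does.

## The treatment-rationale model

A treatment rationale (TR) is an explanation of why a treatment was
recommended for — or argued against — a patient, captured as one
sentence of controlled biomedical English. The controlled-English text
is the primary, lossless record: it is what vetters read and approve,
and it travels verbatim (`source_bce`) on every structured row compiled
from it. Compilation is a projection for one consumer (the treatment
ranker); other consumers could compile the same text differently, which
is why nothing downstream is allowed to discard or rewrite it. Two
mechanisms enforce this: the `TreatmentRationale.bce_text` attribute is
write-once, and the journal's content hash covers the verbatim text, so
any alteration changes the record's identity.

A rationale's lifecycle is a small state machine —
`UNVETTED → {VETTED, REJECTED}`, `VETTED → PUBLISHED` — with every other
transition rejected. Publication requires `VETTED` plus a RELEASE
decision from the vetting store; published content is immutable.

## Evidence model

Evidence strength is the seven-level ordinal scale

`IN_VITRO < IN_VIVO < CASE_REPORT < PHASE_I < PHASE_II < PHASE_III_RCT
< META_ANALYSIS`

together with a study model (`PRECLINICAL` for the first two levels,
`HUMAN_CLINICAL` otherwise) and a case count `n ≥ 1`. Classification of
a compiled sentence works through three cues, in priority order:

1. an explicit trial-type phrase, mapped through the phrase→level table
   (`data/evidence_phrases.tsv`, longest pattern wins; TSV-swappable);
   an explicit participant count ("with N patients") supplies `n`;
2. a single-patient narrative shape ("This … tumor was …"), classified
   as a clinical series with one patient: `CASE_REPORT`, `n = 1`,
   `HUMAN_CLINICAL`;
3. no cue at all: the same conservative `CASE_REPORT`/`n = 1` default,
   but with `evidence_assumed = true` so consumers can filter.

Two scale placements were genuinely open and are fixed here by
convention: "randomized controlled trial" (no phase stated) maps to
`PHASE_III_RCT`, and a non-randomized "clinical series" with `n > 1`
sits at `CASE_REPORT` rank with its stated `n`. Both live in the
swappable phrase table, not in code, precisely because they are
conventions.

## Lexicon and open vocabulary

The concept dictionary is a flat TSV (surface → concept id, preferred
name, category) with case-insensitive lookup and synonym support. The
bundled `data/lexicon_synthetic.tsv` is a **synthetic** ~95-entry
stand-in for a full clinical thesaurus — enough drugs, genes,
alterations, diseases and trial phrases to cover the grammar and the
examples; a real thesaurus export loads through the same interface.
A surface bound to conflicting concepts or categories is rejected at
load time, because silent last-writer-wins resolution would make
compilation order-dependent.

Clinical language is open-ended, so unknown terms never fail hard.
A declared suffix/shape heuristic assigns every non-empty string a
rough part-of-speech (all digits → NUMBER; citation shape → CITATION;
-ize/-ated… → VERBISH; -ly/-ive/-ous… → MODIFIER; anything with an
alphanumeric, including multi-word phrases → NOUNISH; else UNKNOWN).
In the grammar, a `@CATEGORY` slot accepts an unknown NOUNISH token at
a *fallback* cost of 1; parses are ordered fewest-fallbacks-first.
Compiled concepts that miss the lexicon get `LOCAL:<sha256[:12]>` ids
hashed from the whitespace/case-normalized phrase, so the same novel
fusion mentioned in two rationales lands on the same concept id and the
rows stay joinable for ranking.

## Tokenizer and parser

Tokenization is lossless: tokens carry 0-based half-open character
spans, and `detokenize` reproduces the input byte-for-byte (property
tested over arbitrary unicode). Three shape rules matter: a
parenthesized span containing a year or a `vol:page` reference becomes
one CITATION token; hyphens and apostrophes are word-internal (so
`EIF2AK3-alk` and `male's` stay single words, and typographic
apostrophes are normalized only at grammar-match time, never in the
stored text); every other non-space character is its own punctuation
token.

Before parsing, a lexical pass merges multi-word lexicon surfaces
("lung cancer") into single units, greedily longest-first.
OTHER-category surfaces (trial phrases and similar function vocabulary)
are deliberately *not* merged, because the grammar consumes those
word-by-word as terminals. This greedy merge is not backtrackable — a
sentence needing "lung" and "cancer" as separate grammar terminals
would lose that parse — an accepted simplification for a controlled
language.

The parser is an agenda-driven, bottom-up chart parser producing a
packed forest: complete constituents are shared by (symbol, span);
partial edges are deduplicated by (rule, dot, span, children). This
keeps the chart finite even under cyclic unit rules (`A -> B`,
`B -> A`). Tree extraction enumerates the forest and cuts any
derivation that revisits a (symbol, span) already on its own ancestor
path, so the returned parse *set* is finite and well defined; the test
suite checks it equals an independent exhaustive derivation enumerator
on hundreds of random toy grammars. Ambiguity is resolved by a
deterministic total order — fewest fallbacks, then a lexicographic
derivation key — and downstream consumers take the first parse.
Bottom-up parsing with open vocabulary is known to over-generate
lexical hypotheses; a predictive (top-down or trained) parser would
handle that better, and the design keeps the parser swappable behind
`parse_text`.

The grammar file format is one `LHS -> sym sym …` rule per line with
`#` comments; the first LHS is the start symbol. An ALL-CAPS rhs symbol
that is never defined draws a warning, not an error — grammars under
development stay loadable. The bundled grammar covers the trial-backed
declarative form (optionally with participant count, stage-qualified
population and citation), the single-patient case narrative (optional
hedging adverb, optional stage), simple declaratives in both
argument orders, and drug conjunctions with "and".

## Compilation

Compilation is a tree walk keyed on grammar symbol names — the symbol
contract (`BIOMARKER`, `@DISEASE`, `DRUGS`, `EFFECT`/`EFFECTED`,
`TRIALPHRASE`, `NPATIENTS`, `AGE`, `STAGE`, `SEXPOSS`, `%CITATION`) is
the interface between grammar authors and the compiler. Each filled
slot records its character span. Required slots are biomarker, drug and
effect; a parse lacking one raises `MissingSlot` naming it. One
assertion is emitted per conjoined drug, with evidence fields shared.
Design points worth stating:

* the *first* `@DISEASE` leaf is the assertion's disease (the "in
  ⟨disease⟩" context); a later stage-qualified trial population
  contributes the stage but does not override the disease;
* hedging adverbs ("apparently") remain in the verbatim source but do
  not weaken the compiled effect — the vetting stage, not the compiler,
  is where confidence is judged;
* patient demographics (age, sex) stated by a narrative are stored on
  the assertion as contextual fields; they describe the originating
  case, not the assertion's scope;
* citations are stored verbatim (including parentheses) plus a
  URL-encoded scholar-search link-out.

## Vetting

Scores are four three-point Likert dimensions — agreement, generality,
importance, level of evidence — one record per (rationale, vetter),
with resubmission replacing. Aggregation is by **median**: the scale is
ordinal, and a median is robust to one outlying vetter. The release
decision under a policy (quorum, minimum median agreement, whether
de-identification is mandatory) is: HOLD below quorum; REJECT when the
median agreement is 1; RELEASE when quorum, agreement and
de-identification are all satisfied; otherwise HOLD. The default policy
(quorum 1, minimum agreement 2, de-identification required) is a
deliberately light best guess — deployments are expected to override it
via the YAML policy file. Vetter identities are stored (the store is
not anonymous at the data level) but only the aggregate summary is
published with a record; per-vetter detail stays local.

The de-identification screen is a declared rule set, not a compliance
tool: calendar dates (month-name and numeric forms), identifier-like
digit runs of 6+, capitalized name bigrams after a personal title
(Mr/Mrs/Ms/Dr/Prof), and ages ≥ 90 (an age that narrow identifies).
Ages below 90, disease stages and genomic terms pass. Citation-shaped
parentheticals are masked before the date rules run, because a
literature citation's date is provenance, not patient data. The screen
is pure and deterministic, and the suite checks zero false fails over
the synthetic corpus.

## Journal

Published records have three sections mirroring nanopublication's named
graphs: assertion (verbatim text + compiled rows), provenance (case
reference, citation link-outs, vetting summary) and pubinfo (journal
metadata). The record id is `np-<sha256>` over the canonical JSON
(sorted keys, UTF-8, no insignificant whitespace) of assertion +
provenance: identical content ⇒ identical id; any edit ⇒ a new id.
Publication is refused for unvetted rationales and for records with
neither a case reference nor a citation (provenance totality).
Corrections never mutate content: a new record is published and the old
record's `superseded_by` — pubinfo, outside the hash — points forward;
knowledge-base export skips superseded records. Storage is a local
append-only directory of JSON files, one per record, deliberately
detached from any live publication network; an optional TriG export
renders the three named graphs for linked-data consumers.

## Ranking

An assertion matches a profile when its biomarker concept id is in the
profile's biomarker set and its disease restriction (if any) equals the
profile's diagnosis id. Matching is flat: `NSCLC` matches `lung cancer`
only if the lexicon maps them to one concept — there is no ontology
traversal, consistent with the flat lexicon.

Each matching assertion contributes `w = L(level) × (1 + log10 n)`.
The per-level multiplier table `L` defaults to the rank 1…7 and is
TSV-swappable; the case transform is logarithmic so that the weight is
monotone in both factors, a ten-fold larger series exactly doubles the
case multiplier, and `n = 1` contributes exactly `L(level)` — a scoring
definition chosen for these monotonicity properties rather than derived
from any published coefficient set. A drug's score is
`Σ w(sensitivity) − Σ w(resistance)` (difference, not ratio: it keeps
cancellation exact and the score linear in added evidence), ranked
descending with alphabetical tie-break. Every assertion contributes
independently; multiple rationales deriving from the same source are
*not* deduplicated. That independence assumption is wrong in practice
and is the model's most important known limitation.

## Synthetic corpus and what tests show

Real tumor-board transcripts cannot be shipped, so test corpora are
sampled from the grammar itself: seeded top-down expansion with uniform
rule choice, truncated at a derivation-depth bound (default 24, retried
on truncation), category slots filled from pools drawn from the bundled
lexicon. Defaults chosen to look like plausible capture data: trial
sizes 10–500, ages 18–89 (so a clean corpus passes the
de-identification screen), stages 1–4, plus two deliberately
unlexiconed fusion names in the gene pool so the open-vocabulary
fallback is exercised routinely. The trial-phrase pool comes from the
grammar rather than the lexicon so phrases remain terminal-matchable.
Each sentence is paired with the ground-truth slots used to build it.

Because generation and parsing share the grammar, closure results
(every generated sentence parses; compilation recovers the ground-truth
slots) demonstrate the *internal consistency* of the
tokenizer–parser–compiler chain at scale, not coverage of free clinical
speech. Coverage claims rest only on the bundled worked examples and
the hand-written simpler forms in the test suite. Problem sizes used by
the default suite — 200 random toy grammars for the parser oracle,
1,000 generated sentences for closure, 100 random knowledge bases for
the ranking oracle — keep the whole suite in the tens of seconds while
exercising every code path; all are plain constants in the tests and
scale up freely.

## Numerical and degenerate-input choices

* Character offsets are 0-based, half-open, everywhere.
* Score arithmetic is plain float; the ranking decomposition
  (`score = Σ pro − Σ contra`) is asserted to 1e-9.
* Empty input: tokenizing "" yields no tokens; parsing an empty token
  sequence yields no parses (an empty list is the no-parse signal, not
  an error); an empty corpus yields an all-zero demo report.
* Ties in ranking break alphabetically by preferred name, then concept
  id; evidence lists sort by weight descending with the source text as
  a deterministic secondary key.
* The demo loop stamps records with logical sequence stamps
  (`seq-000000`, …) instead of wall-clock time, so two runs over the
  same corpus produce byte-identical reports.

## Known limitations

* The grammar covers a narrow band of sentence forms by design;
  out-of-grammar text fails to parse rather than degrade.
* The greedy multi-word lexical merge cannot backtrack.
* The de-identification screen is heuristic; it targets the shapes
  listed above and nothing else.
* Ranking treats all evidence as independent and has no notion of
  source overlap, recency, or dose.
* No ontology reasoning: concept matching is exact-id only.
* The journal is local; pushing records to a live nanopublication
  network, access control, and prospective coordination of treatment
  choices across patients are out of scope.
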