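# trkit — treatment-rationale capture, compilation, vetting, publication and ranking

`trkit` is a library and command-line tool for the informatics loop behind
molecular tumor boards: capturing **treatment rationales** (TRs) — short
explanations of why a treatment was recommended for, or argued against, a
patient — in a restricted, machine-compilable subset of English
(*controlled biomedical English*), compiling them into structured
targeted-therapy assertions, screening and scoring them in a lightweight
vetting step, publishing the vetted records in an immutable,
content-addressed local journal, and ranking candidate drugs for a
patient's molecular profile by evidence-weighted aggregation.

It is aimed at clinical-informatics researchers prototyping
rapid-learning decision support: people who need the whole
capture → compile → vet → publish → rank loop runnable, testable and
scriptable, without a live deployment, an EHR integration, or a full
clinical thesaurus.

## The model

**Assertions.** Each rationale compiles into one or more rows of a
targeted-therapy knowledge base:

> *biomarker × disease × drug × effect* (sensitivity / resistance),

annotated with an ordinal **evidence level**

> in&nbsp;vitro < in&nbsp;vivo < case&nbsp;report < phase&nbsp;I < phase&nbsp;II
> < phase&nbsp;III&nbsp;RCT < meta-analysis,

a **model** (preclinical vs human/clinical) and a **case count** *n*.
A single-patient tumor-board observation is a clinical series with
*n* = 1: `CASE_REPORT`, `HUMAN_CLINICAL`, `cases = 1`. The verbatim
source sentence travels on every row (`source_bce`) — the controlled
English is the lossless record; the compiled row is a projection.

**Parsing.** Sentences are parsed bottom-up by an agenda-driven chart
parser over a plain-text context-free grammar (a few dozen rules).
Vocabulary is open-ended: tokens bound to lexicon concepts fill
`@CATEGORY` slots directly; unknown noun-ish tokens (novel gene fusions,
diets, ...) fill them at a *fallback* cost and receive stable
`LOCAL:<hash>` concept ids, so parses are ordered fewest-fallbacks-first
and unlexiconed concepts stay joinable.

**Ranking.** For a patient profile (diagnosis + biomarker set), each
matching assertion contributes independently a weight

```
w = L(level) × (1 + log10(cases))
```

with a configurable per-level multiplier `L` (default 1…7 along the
ordinal scale). A drug's score is `Σ w(pro) − Σ w(contra)`; drugs are
ranked by score with full pro/contra evidence attached.

## Worked example

Compile a single-patient case narrative:

```bash
trkit compile "This 50 year old male’s stage 4 NSCLC tumor was apparently sensitized to ceritinib by an EIF2AK3-alk fusion."
```

prints one assertion (abridged):

```json
{
  "biomarker": {"concept_id": "LOCAL:cf864e2bb7fc", "preferred_name": "EIF2AK3-alk fusion"},
  "disease":   {"concept_id": "NCIT:C2926", "preferred_name": "Non-Small Cell Lung Carcinoma"},
  "stage": 4,
  "drug":      {"concept_id": "NCIT:C95703", "preferred_name": "Ceritinib"},
  "effect": "SENSITIVITY",
  "model": "HUMAN_CLINICAL",
  "evidence_level": "CASE_REPORT",
  "cases": 1,
  "age": 50,
  "sex": "male"
}
```

The narrative form has no trial-type cue, so it is classified as a
one-case human/clinical observation; the hedge ("apparently") stays in
the verbatim source but does not change the compiled effect; the novel
fusion gets a local content-hash concept id.

Run the whole loop over the two bundled example sentences (the same
case narrative plus a trial-backed declarative sentence with 200
randomized-trial patients):

```bash
trkit demo --n 0
```

```json
{
  "captured": 2, "parsed": 2, "compiled": 2,
  "released": 2, "held": 0, "rejected": 0, "published": 2,
  "kb_size": 2,
  "ranking": [{"drug": "Ceritinib", "score": 22.80618, "pro": 2, "contra": 0}]
}
```

Both sentences pass the de-identification screen and the default
vetting policy, are published, and export into a two-row knowledge
base. Ceritinib's score decomposes as `3 × (1 + log10 1) = 3.0` for the
case report plus `6 × (1 + log10 200) ≈ 19.806` for the phase-III RCT
with 200 patients: 22.80618.

Other verbs: `trkit parse`, `trkit vet deid|score|decide`,
`trkit journal fetch|query|export`, `trkit rank --profile p.yaml --kb
kb.jsonl`, `trkit generate --seed N` (synthetic corpus).

## Layout

| Module | Role |
| --- | --- |
| `trkit.core_model` | shared domain types, evidence-level order, record validation, JSONL knowledge base |
| `trkit.lexicon` | pluggable concept dictionary (TSV) + open-vocabulary fallback tagger |
| `trkit.bce_parser` | lossless tokenizer, grammar loader, bottom-up chart parser |
| `trkit.bce_compiler` | parse tree → slot frame → targeted-therapy assertions |
| `trkit.vetting` | de-identification screen, Likert scoring, release decisions |
| `trkit.nanojournal` | immutable content-addressed journal, querying, KB/TriG export |
| `trkit.trex` | evidence-weighted treatment ranking |
| `trkit.corpus` | bundled fixtures, synthetic corpus generator, demo loop |
| `trkit.cli` | the `trkit` command |

See `docs/methods.md` for the underlying assumptions, parameter
defaults, numerical choices and known limitations.
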