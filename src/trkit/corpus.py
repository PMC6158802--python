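"""Bundled defaults, grammar-driven synthetic corpus generation, and the
end-to-end capture→compile→vet→publish→rank demonstration loop.

The generator exists because real tumor-board transcripts cannot be
shipped: it samples sentences top-down from the same grammar the parser
loads, filling category slots from pools drawn from the bundled
lexicon, and returns each sentence paired with the ground-truth slots
used to fill it. That makes generate-then-parse closure and
compile-round-trip testable at any scale, at the cost that generated
sentences share the grammar's structure by construction — they probe
the pipeline's correctness, not its coverage of free clinical speech.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .bce_compiler import EvidenceTable, compile_tree, load_evidence_table
from .bce_parser import Grammar, load_grammar, parse_text
from .core_model import (
    Concept,
    Effect,
    PatientProfile,
    Polarity,
    TreatmentRationale,
)
from .lexicon import Lexicon, load_lexicon
from .nanojournal import NanoJournal
from .trex import rank_treatments
from .vetting import (
    DEFAULT_POLICY,
    Decision,
    ReleasePolicy,
    VettingRecord,
    VettingStore,
    deid_check,
)

# ---------------------------------------------------------------------------
# Bundled resources
# ---------------------------------------------------------------------------

_cache: dict = {}


def _data_path(name: str):
    return resources.files("trkit") / "data" / name


def default_lexicon() -> Lexicon:
    """The bundled synthetic mini-thesaurus (see data/lexicon_synthetic.tsv)."""
    if "lexicon" not in _cache:
        with resources.as_file(_data_path("lexicon_synthetic.tsv")) as p:
            _cache["lexicon"] = load_lexicon(p)
    return _cache["lexicon"]


def default_grammar() -> Grammar:
    if "grammar" not in _cache:
        with resources.as_file(_data_path("grammar.bce")) as p:
            _cache["grammar"] = load_grammar(p)
    return _cache["grammar"]


def default_evidence_table() -> EvidenceTable:
    if "evidence" not in _cache:
        with resources.as_file(_data_path("evidence_phrases.tsv")) as p:
            _cache["evidence"] = load_evidence_table(p)
    return _cache["evidence"]


def example_sentences() -> list[str]:
    """The two bundled worked-example rationales, verbatim."""
    text = _data_path("example_trs.txt").read_text(encoding="utf-8")
    return [
        line for line in text.splitlines() if line.strip() and not line.startswith("#")
    ]


# ---------------------------------------------------------------------------
# Synthetic corpus generation
# ---------------------------------------------------------------------------


@dataclass
class GenerationConfig:
    """Sampling configuration for the synthetic corpus.

    Pools default to the bundled lexicon's surfaces per category (plus a
    couple of deliberately unlexiconed fusion names to exercise the
    open-vocabulary fallback); the trial-phrase pool comes from the
    grammar itself so phrases stay terminal-matchable.
    """

    seed: int = 0
    n_sentences: int = 100
    max_depth: int = 24
    pools: Optional[dict[str, list[str]]] = None

    def __post_init__(self):
        if self.n_sentences < 0:
            raise ValueError("n_sentences must be ≥ 0")
        if self.max_depth < 1:
            raise ValueError("max_depth must be ≥ 1")


#: Unlexiconed biomarker names included in the default gene pool so the
#: generated corpus exercises unknown-word fallbacks, as live capture would.
NOVEL_GENE_NAMES = ["EML4-ALK", "CD74-ROS1"]

_NUMBER_RANGES = {"NPATIENTS": (10, 500), "AGE": (18, 89), "STAGE": (1, 4)}

_SURNAMES = [
    "Adler", "Baker", "Chen", "Dunn", "Evans", "Foster", "Gray", "Hart",
    "Ito", "Jones", "Klein", "Lund", "Moss", "Nolan", "Owens", "Park",
]
_JOURNALS = ["J Clin Invest", "BMC Res Notes", "Ann Intern Res", "Clin Sci Rep"]


class GenerationError(RuntimeError):
    pass


def default_pools(lexicon: Optional[Lexicon] = None) -> dict[str, list[str]]:
    lex = lexicon if lexicon is not None else default_lexicon()
    pools = {
        cat: lex.surfaces(cat) for cat in ("DRUG", "GENE", "ALTERATION", "DISEASE")
    }
    pools["GENE"] = pools["GENE"] + sorted(NOVEL_GENE_NAMES)
    return pools


@dataclass
class GeneratedTR:
    """A sampled sentence plus the ground-truth slots used to build it."""

    text: str
    truth: dict


def _make_citation(rng: random.Random) -> str:
    names = rng.sample(_SURNAMES, 2)
    journal = rng.choice(_JOURNALS)
    year = rng.randint(1995, 2018)
    vol = rng.randint(1, 60)
    page = rng.randint(1, 2000)
    return f"({names[0]} and {names[1]}, {journal}. {year};{vol}:{page})"


def _expand(
    sym: str,
    grammar: Grammar,
    rng: random.Random,
    pools: dict[str, list[str]],
    truth: dict,
    parent: str,
    depth: int,
) -> list[str]:
    if depth < 0:
        raise GenerationError("derivation exceeded max_depth")
    if sym == "%NUMBER":
        lo, hi = _NUMBER_RANGES.get(parent, (1, 9))
        value = rng.randint(lo, hi)
        if parent == "NPATIENTS":
            truth["cases"] = value
        elif parent == "AGE":
            truth["age"] = value
        elif parent == "STAGE" and "stage" not in truth:
            truth["stage"] = value
        return [str(value)]
    if sym == "%CITATION":
        citation = _make_citation(rng)
        truth["citation"] = citation
        return [citation]
    if sym.startswith("@"):
        category = sym[1:]
        pool = pools.get(category)
        if not pool:
            raise GenerationError(f"no pool for category {category}")
        value = rng.choice(pool)
        if category == "DISEASE":
            truth.setdefault("diseases", []).append(value)
        elif category == "DRUG":
            truth.setdefault("drugs", []).append(value)
        else:
            truth.setdefault("biomarker_parts", []).append(value)
        return [value]
    return [sym]


_TRACKED_PHRASES = {
    "EFFECT": "effect_word",
    "EFFECTED": "effect_word",
    "TRIALPHRASE": "trial_phrase",
    "BIOMARKER": "biomarker",
    "SEXPOSS": "sex_word",
}


def _expand_tracked(
    sym: str,
    grammar: Grammar,
    rng: random.Random,
    pools: dict[str, list[str]],
    truth: dict,
    parent: str,
    depth: int,
) -> list[str]:
    """Like :func:`_expand` but records the surface text of slot-bearing
    subtrees (biomarker phrase, effect word, trial phrase, sex)."""
    if sym in grammar.nonterminals and sym in _TRACKED_PHRASES:
        if depth < 0:
            raise GenerationError("derivation exceeded max_depth")
        rule = rng.choice(grammar.rules_for[sym])
        out: list[str] = []
        for child in rule.rhs:
            out.extend(
                _expand_tracked(child, grammar, rng, pools, truth, sym, depth - 1)
            )
        truth[_TRACKED_PHRASES[sym]] = " ".join(out)
        return out
    if sym in grammar.nonterminals:
        if depth < 0:
            raise GenerationError("derivation exceeded max_depth")
        rule = rng.choice(grammar.rules_for[sym])
        out = []
        for child in rule.rhs:
            out.extend(
                _expand_tracked(child, grammar, rng, pools, truth, sym, depth - 1)
            )
        return out
    return _expand(sym, grammar, rng, pools, truth, parent, depth)


def _join(tokens: Sequence[str]) -> str:
    text = " ".join(tokens)
    return re.sub(r"\s+([,.;:])", r"\1", text)


def generate_corpus(
    cfg: GenerationConfig,
    grammar: Optional[Grammar] = None,
    lexicon: Optional[Lexicon] = None,
) -> list[GeneratedTR]:
    """Sample *n_sentences* rationales by seeded top-down expansion with
    uniform rule choice; identical config ⇒ identical corpus."""
    grammar = grammar if grammar is not None else default_grammar()
    pools = cfg.pools if cfg.pools is not None else default_pools(lexicon)
    rng = random.Random(cfg.seed)
    corpus: list[GeneratedTR] = []
    for _ in range(cfg.n_sentences):
        for attempt in range(50):
            truth: dict = {}
            try:
                tokens = _expand_tracked(
                    grammar.start, grammar, rng, pools, truth, "", cfg.max_depth
                )
                break
            except GenerationError:
                continue
        else:
            raise GenerationError(
                f"grammar not expandable within max_depth={cfg.max_depth}"
            )
        truth["disease"] = (truth.get("diseases") or [None])[0]
        truth.setdefault("drugs", [])
        if "effect_word" in truth:
            word = truth["effect_word"].lower()
            truth["effect"] = (
                Effect.RESISTANCE.value
                if "resist" in word
                else Effect.SENSITIVITY.value
            )
        if "sex_word" in truth:
            truth["sex"] = truth["sex_word"].replace("’", "'").lower().removesuffix("'s")
        corpus.append(GeneratedTR(_join(tokens), truth))
    return corpus


# ---------------------------------------------------------------------------
# End-to-end demonstration loop
# ---------------------------------------------------------------------------


def run_demo_loop(
    sentences: Sequence[str],
    policy: ReleasePolicy = DEFAULT_POLICY,
    weights=None,
    grammar: Optional[Grammar] = None,
    lexicon: Optional[Lexicon] = None,
    journal: Optional[NanoJournal] = None,
    profile: Optional[PatientProfile] = None,
    auto_score: int = 3,
) -> dict:
    """Run the full rapid-learning loop over *sentences*:
    capture → compile → vet (auto-scored) → publish → export → rank.

    Returns a summary report with per-stage counts (conserved:
    ``published + held + rejected == captured``) and the final ranking.
    Sentences that fail to parse, fail the de-identification screen, or
    fail to compile are held, never silently dropped.
    """
    grammar = grammar if grammar is not None else default_grammar()
    lexicon = lexicon if lexicon is not None else default_lexicon()
    journal = journal if journal is not None else NanoJournal()
    store = VettingStore()
    report = {
        "captured": len(sentences),
        "parsed": 0,
        "compiled": 0,
        "released": 0,
        "held": 0,
        "rejected": 0,
        "published": 0,
        "stage_errors": [],
    }
    published_assertions = []
    for i, text in enumerate(sentences):
        tr_id = f"tr-{i:06d}"
        store.track(tr_id)
        trees = parse_text(text, grammar, lexicon=lexicon)
        if not trees:
            report["held"] += 1
            report["stage_errors"].append({"tr_id": tr_id, "stage": "parse"})
            continue
        report["parsed"] += 1
        try:
            assertions = compile_tree(
                trees[0], text, lexicon=lexicon, provenance_id=tr_id
            )
        except ValueError as exc:
            report["held"] += 1
            report["stage_errors"].append(
                {"tr_id": tr_id, "stage": "compile", "error": str(exc)}
            )
            continue
        report["compiled"] += 1
        polarity = (
            Polarity.CONTRA
            if all(a.effect == Effect.RESISTANCE for a in assertions)
            else Polarity.PRO
        )
        tr = TreatmentRationale(
            tr_id, text, polarity=polarity, case_ref=f"case-{i:06d}",
            assertions=assertions,
        )
        deid = deid_check(text)
        store.record_score(
            tr,
            VettingRecord(
                tr_id=tr_id,
                vetter_id="auto-vetter",
                agreement=auto_score,
                generality=auto_score,
                importance=auto_score,
                evidence=auto_score,
                bce_ok=True,
                deid_ok=deid.ok,
            ),
        )
        decision = store.release_decision(tr_id, policy)
        if decision == Decision.REJECT:
            tr.mark_rejected()
            report["rejected"] += 1
            continue
        if decision == Decision.HOLD:
            report["held"] += 1
            report["stage_errors"].append({"tr_id": tr_id, "stage": "vetting"})
            continue
        report["released"] += 1
        tr.mark_vetted()
        journal.publish(tr, store.summary(tr_id), timestamp=f"seq-{i:06d}")
        report["published"] += 1
        published_assertions.extend(assertions)

    kb = journal.export_kb()
    if profile is None and kb:
        diseases = [a.disease for a in kb if a.disease is not None]
        diagnosis = diseases[0] if diseases else Concept("LOCAL:any", "any", "DISEASE")
        profile = PatientProfile(
            diagnosis=diagnosis,
            biomarkers=frozenset(a.biomarker for a in kb),
        )
    ranking = rank_treatments(profile, kb, weights) if profile is not None else []
    report["kb_size"] = len(kb)
    report["ranking"] = [
        {"drug": r.drug.preferred_name, "score": round(r.score, 6),
         "pro": len(r.pro), "contra": len(r.contra)}
        for r in ranking
    ]
    return report


def report_json(report: dict) -> str:
    return json.dumps(report, indent=2, ensure_ascii=False)
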