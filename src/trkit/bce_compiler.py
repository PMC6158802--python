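"""Compile parse trees of controlled-English rationales into structured
targeted-therapy assertions.

Compilation is a grammar-annotated tree walk: the grammar's symbol names
are a contract (``BIOMARKER``, ``@DISEASE``, ``DRUGS``, ``EFFECT`` /
``EFFECTED``, ``TRIALPHRASE``, ``NPATIENTS``, ``AGE``, ``STAGE``,
``SEXPOSS``, ``%CITATION``) and the compiler collects the surface text
under each into a :class:`SlotFrame`, every filled slot keeping its
character span in the source.

Evidence classification follows the ordinal evidence scale: an explicit
trial-type phrase is mapped through a configurable phrase→level table
and an explicit participant count becomes the case count; a
single-patient narrative ("this ... patient/tumor") is a clinical
series of one — a case report with ``cases = 1`` on a human/clinical
model; with no evidence cue at all the same conservative default is
used and the assertion is flagged as assumed.

The verbatim source text travels with every assertion (``source_bce``):
compilation is a lossy projection, the controlled-English sentence is
the lossless record.
"""

from __future__ import annotations

import csv
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .bce_parser import ParseTree
from .core_model import (
    Citation,
    Concept,
    Effect,
    EvidenceLevel,
    EvidenceModel,
    TTDAssertion,
    coerce_level,
)
from .lexicon import Lexicon, local_concept_id

_EFFECT_WORDS = {
    "sensitivity": Effect.SENSITIVITY,
    "sensitized": Effect.SENSITIVITY,
    "sensitizes": Effect.SENSITIVITY,
    "resistance": Effect.RESISTANCE,
    "resistant": Effect.RESISTANCE,
}

_PRECLINICAL_LEVELS = frozenset({EvidenceLevel.IN_VITRO, EvidenceLevel.IN_VIVO})


class MissingSlotError(ValueError):
    """A required slot (biomarker, drug or effect) is absent."""

    def __init__(self, slot: str):
        self.slot = slot
        super().__init__(f"required slot missing: {slot}")


@dataclass(frozen=True)
class SlotValue:
    """An extracted slot value plus its source character span."""

    value: object
    span: tuple[int, int]


@dataclass
class SlotFrame:
    """Slots extracted from one parsed sentence. ``drugs`` holds one
    entry per conjoined drug; the other slots are single-valued."""

    biomarker: Optional[SlotValue] = None
    disease: Optional[SlotValue] = None
    stage: Optional[SlotValue] = None
    drugs: list[SlotValue] = field(default_factory=list)
    effect: Optional[SlotValue] = None
    trial_phrase: Optional[SlotValue] = None
    cases: Optional[SlotValue] = None
    age: Optional[SlotValue] = None
    sex: Optional[SlotValue] = None
    citation: Optional[SlotValue] = None
    narrative: bool = False  # single-patient "this ... tumor/patient" form

    @property
    def drug(self) -> Optional[SlotValue]:
        return self.drugs[0] if self.drugs else None


@dataclass(frozen=True)
class EvidenceCall:
    level: EvidenceLevel
    cases: int
    model: EvidenceModel
    assumed: bool = False  # no explicit evidence cue in the sentence


# ---------------------------------------------------------------------------
# Phrase -> evidence-level table
# ---------------------------------------------------------------------------


class EvidenceTable:
    """Ordered substring patterns mapping trial-type phrases to levels.

    Longest pattern wins; matching is case-insensitive on normalized
    whitespace. The table is a plain TSV (``pattern\tlevel``) so a
    deployment can swap in its own trigger phrases.
    """

    def __init__(self, entries: list[tuple[str, EvidenceLevel]]):
        self.entries = sorted(
            ((p.lower().strip(), lvl) for p, lvl in entries),
            key=lambda e: (-len(e[0]), e[0]),
        )

    def classify(self, phrase: str) -> Optional[EvidenceLevel]:
        norm = " ".join(phrase.lower().split())
        for pattern, level in self.entries:
            if pattern in norm:
                return level
        return None


def load_evidence_table(path: Union[str, Path]) -> EvidenceTable:
    entries: list[tuple[str, EvidenceLevel]] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["pattern", "level"]:
            raise ValueError(f"{path}: expected header 'pattern\\tlevel'")
        for lineno, row in enumerate(reader, start=2):
            if not row or not row[0].strip():
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            entries.append((row[0], coerce_level(row[1].strip())))
    return EvidenceTable(entries)


# ---------------------------------------------------------------------------
# Tree walk -> slot frame
# ---------------------------------------------------------------------------


def _subtree_text(node: ParseTree, source: str) -> tuple[str, tuple[int, int]]:
    start, end = node.span
    return source[start:end], (start, end)


def _first_number(node: ParseTree) -> Optional[int]:
    for leaf in node.leaves:
        if leaf.symbol == "%NUMBER":
            return int(leaf.unit.text)
    return None


def fill_frame(tree: ParseTree, source: str) -> SlotFrame:
    """Collect slot values from a complete parse by symbol contract."""
    frame = SlotFrame()

    biomarkers = tree.find_all("BIOMARKER")
    if biomarkers:
        text, span = _subtree_text(biomarkers[0], source)
        frame.biomarker = SlotValue(text, span)

    seen_drug_spans = set()
    for leaf in tree.find_leaves("@DRUG"):
        if leaf.unit.span not in seen_drug_spans:
            seen_drug_spans.add(leaf.unit.span)
            frame.drugs.append(SlotValue(leaf.unit.text, leaf.unit.span))

    disease_leaves = tree.find_leaves("@DISEASE")
    if disease_leaves:
        leaf = disease_leaves[0]
        frame.disease = SlotValue(leaf.unit.text, leaf.unit.span)

    for sym in ("EFFECT", "EFFECTED"):
        nodes = tree.find_all(sym)
        if nodes:
            text, span = _subtree_text(nodes[0], source)
            key = next((w for w in text.lower().split() if w in _EFFECT_WORDS), None)
            if key is not None:
                frame.effect = SlotValue(_EFFECT_WORDS[key], span)
            break

    trial = tree.find_all("TRIALPHRASE")
    if trial:
        text, span = _subtree_text(trial[0], source)
        frame.trial_phrase = SlotValue(text, span)

    npat = tree.find_all("NPATIENTS")
    if npat:
        num = _first_number(npat[0])
        if num is not None:
            frame.cases = SlotValue(num, npat[0].span)

    age = tree.find_all("AGE")
    if age:
        num = _first_number(age[0])
        if num is not None:
            frame.age = SlotValue(num, age[0].span)

    stage = tree.find_all("STAGE")
    if stage:
        num = _first_number(stage[0])
        if num is not None:
            frame.stage = SlotValue(num, stage[0].span)

    sex = tree.find_all("SEXPOSS")
    if sex:
        text, span = _subtree_text(sex[0], source)
        frame.sex = SlotValue(
            text.replace("’", "'").lower().removesuffix("'s"), span
        )

    for leaf in tree.leaves:
        if leaf.symbol == "%CITATION":
            frame.citation = SlotValue(leaf.unit.text, leaf.unit.span)
            break

    leaves = tree.leaves
    frame.narrative = bool(
        tree.find_all("CASE_TR")
        or (leaves and leaves[0].unit.text.lower() == "this")
    )
    return frame


# ---------------------------------------------------------------------------
# Evidence classification
# ---------------------------------------------------------------------------


def classify_evidence(frame: SlotFrame, table: EvidenceTable) -> EvidenceCall:
    """Evidence level, case count and model for a filled slot frame."""
    if frame.cases is not None and int(frame.cases.value) <= 0:
        raise ValueError(f"stated case count must be positive, got {frame.cases.value}")

    assumed = False
    if frame.trial_phrase is not None:
        level = table.classify(str(frame.trial_phrase.value))
        if level is None:
            level = EvidenceLevel.CASE_REPORT
            assumed = True
        cases = int(frame.cases.value) if frame.cases is not None else 1
    elif frame.narrative or frame.age is not None or frame.sex is not None:
        # single-patient narrative: a clinical series with n = 1
        level = EvidenceLevel.CASE_REPORT
        cases = int(frame.cases.value) if frame.cases is not None else 1
    else:
        level = EvidenceLevel.CASE_REPORT
        cases = int(frame.cases.value) if frame.cases is not None else 1
        assumed = True

    model = (
        EvidenceModel.PRECLINICAL
        if level in _PRECLINICAL_LEVELS
        else EvidenceModel.HUMAN_CLINICAL
    )
    return EvidenceCall(level, cases, model, assumed)


# ---------------------------------------------------------------------------
# Citation linkout
# ---------------------------------------------------------------------------

SCHOLAR_URL = "https://scholar.google.com/scholar?q="


def extract_citation(frame: SlotFrame) -> Optional[Citation]:
    """Verbatim citation text plus a scholar-search URL, or ``None``."""
    if frame.citation is None:
        return None
    text = str(frame.citation.value)
    query = text.strip("()")
    return Citation(text=text, url=SCHOLAR_URL + urllib.parse.quote_plus(query))


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def _concept(text: str, lexicon: Optional[Lexicon], default_category: str) -> Concept:
    if lexicon is not None:
        b = lexicon.lookup(text)
        if b is not None:
            return Concept(b.concept_id, b.preferred_name, b.category)
    return Concept(local_concept_id(text), text, default_category)


def compile_tree(
    tree: ParseTree,
    source: str,
    lexicon: Optional[Lexicon] = None,
    evidence_table: Optional[EvidenceTable] = None,
    provenance_id: str = "",
) -> list[TTDAssertion]:
    """Compile a complete parse of *source* into assertions, one per
    (biomarker, drug, effect) triple; evidence fields are shared."""
    if evidence_table is None:
        from .corpus import default_evidence_table

        evidence_table = default_evidence_table()
    frame = fill_frame(tree, source)
    if frame.biomarker is None:
        raise MissingSlotError("biomarker")
    if not frame.drugs:
        raise MissingSlotError("drug")
    if frame.effect is None:
        raise MissingSlotError("effect")

    call = classify_evidence(frame, evidence_table)
    citation = extract_citation(frame)
    biomarker = _concept(str(frame.biomarker.value), lexicon, "ALTERATION")
    disease = (
        _concept(str(frame.disease.value), lexicon, "DISEASE")
        if frame.disease is not None
        else None
    )

    assertions = []
    for drug_slot in frame.drugs:
        assertions.append(
            TTDAssertion(
                biomarker=biomarker,
                drug=_concept(str(drug_slot.value), lexicon, "DRUG"),
                effect=frame.effect.value,
                model=call.model,
                evidence_level=call.level,
                cases=call.cases,
                source_bce=source,
                provenance_id=provenance_id,
                disease=disease,
                stage=int(frame.stage.value) if frame.stage is not None else None,
                citation=citation,
                age=int(frame.age.value) if frame.age is not None else None,
                sex=str(frame.sex.value) if frame.sex is not None else None,
                evidence_assumed=call.assumed,
            )
        )
    return assertions
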