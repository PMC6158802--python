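"""Shared domain model for treatment-rationale knowledge capture.

The unit of knowledge throughout the package is the *treatment rationale*
(TR): a short, controlled-English explanation of why a treatment was
recommended for — or argued against — a patient, typically voiced at a
molecular tumor board. Each TR compiles into one or more targeted-therapy
assertions (:class:`TTDAssertion`): a biomarker × disease × drug ×
effect row annotated with the strength of the supporting evidence.

Evidence strength is an ordinal scale running from bench work to pooled
randomized trials (:class:`EvidenceLevel`). A tumor-board case report
enters the knowledge base as a fully clinical observation with exactly
one case — the smallest possible clinical series — which is why
``CASE_REPORT`` implies a human/clinical model and why ranking weights
grow with both level and case count.

Records are plain dataclasses; validation returns violations as data
(:func:`validate_assertion`) so that a knowledge base can be screened
without raising. The on-disk interchange format for assertion
collections is JSON Lines, one assertion per line, UTF-8.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union


class EvidenceLevel(enum.IntEnum):
    """Ordinal level of evidence, weakest first.

    The integer value is the rank in the total order; ranking weights
    are configured separately (see :mod:`trkit.trex`).
    """

    IN_VITRO = 1
    IN_VIVO = 2
    CASE_REPORT = 3
    PHASE_I = 4
    PHASE_II = 5
    PHASE_III_RCT = 6
    META_ANALYSIS = 7


def coerce_level(level: Union["EvidenceLevel", str]) -> EvidenceLevel:
    """Return *level* as an :class:`EvidenceLevel`, raising ``ValueError``
    for unknown labels."""
    if isinstance(level, EvidenceLevel):
        return level
    try:
        return EvidenceLevel[str(level)]
    except KeyError:
        raise ValueError(f"unknown evidence level: {level!r}") from None


def compare_levels(x: Union[EvidenceLevel, str], y: Union[EvidenceLevel, str]) -> int:
    """Three-way comparison of two evidence levels (-1, 0 or 1)."""
    a, b = coerce_level(x), coerce_level(y)
    return (a > b) - (a < b)


class Effect(str, enum.Enum):
    SENSITIVITY = "SENSITIVITY"
    RESISTANCE = "RESISTANCE"


class EvidenceModel(str, enum.Enum):
    PRECLINICAL = "PRECLINICAL"
    HUMAN_CLINICAL = "HUMAN_CLINICAL"


class Polarity(str, enum.Enum):
    PRO = "PRO"
    CONTRA = "CONTRA"


class TRStatus(str, enum.Enum):
    UNVETTED = "UNVETTED"
    VETTED = "VETTED"
    REJECTED = "REJECTED"
    PUBLISHED = "PUBLISHED"


#: Legal lifecycle transitions for a treatment rationale.
ALLOWED_TRANSITIONS = frozenset(
    {
        (TRStatus.UNVETTED, TRStatus.VETTED),
        (TRStatus.UNVETTED, TRStatus.REJECTED),
        (TRStatus.VETTED, TRStatus.PUBLISHED),
    }
)


@dataclass(frozen=True)
class Concept:
    """A reference to a dictionary concept (or a local stand-in for one)."""

    concept_id: str
    preferred_name: str
    category: str = "OTHER"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Concept":
        return cls(d["concept_id"], d["preferred_name"], d.get("category", "OTHER"))


@dataclass(frozen=True)
class Citation:
    """A verbatim citation string plus a scholar-search lookup URL."""

    text: str
    url: Optional[str] = None

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Citation":
        return cls(d["text"], d.get("url"))


@dataclass
class TTDAssertion:
    """One structured targeted-therapy row: biomarker × disease × drug ×
    effect, with its evidence annotation and verbatim source text.

    ``age`` and ``sex`` are contextual patient demographics carried over
    from single-patient narratives; they describe the originating case,
    not the assertion's scope.
    """

    biomarker: Concept
    drug: Concept
    effect: Effect
    model: EvidenceModel
    evidence_level: EvidenceLevel
    cases: int
    source_bce: str
    provenance_id: str = ""
    disease: Optional[Concept] = None
    stage: Optional[int] = None
    citation: Optional[Citation] = None
    age: Optional[int] = None
    sex: Optional[str] = None
    evidence_assumed: bool = False

    def to_dict(self) -> dict:
        return {
            "biomarker": self.biomarker.to_dict() if self.biomarker else None,
            "disease": self.disease.to_dict() if self.disease else None,
            "stage": self.stage,
            "drug": self.drug.to_dict() if self.drug else None,
            "effect": self.effect.value if self.effect else None,
            "model": self.model.value,
            "evidence_level": self.evidence_level.name,
            "cases": self.cases,
            "citation": self.citation.to_dict() if self.citation else None,
            "source_bce": self.source_bce,
            "provenance_id": self.provenance_id,
            "age": self.age,
            "sex": self.sex,
            "evidence_assumed": self.evidence_assumed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TTDAssertion":
        return cls(
            biomarker=Concept.from_dict(d["biomarker"]),
            drug=Concept.from_dict(d["drug"]),
            effect=Effect(d["effect"]),
            model=EvidenceModel(d["model"]),
            evidence_level=coerce_level(d["evidence_level"]),
            cases=int(d["cases"]),
            source_bce=d["source_bce"],
            provenance_id=d.get("provenance_id", ""),
            disease=Concept.from_dict(d["disease"]) if d.get("disease") else None,
            stage=d.get("stage"),
            citation=Citation.from_dict(d["citation"]) if d.get("citation") else None,
            age=d.get("age"),
            sex=d.get("sex"),
            evidence_assumed=bool(d.get("evidence_assumed", False)),
        )


def validate_assertion(a: TTDAssertion) -> list[str]:
    """Check a fully constructed assertion against the record invariants.

    Returns an empty list when the record is well formed; otherwise a
    list of human-readable violation strings naming the field and rule.
    Violations are data, not exceptions.
    """
    violations: list[str] = []
    if a.biomarker is None:
        violations.append("biomarker: required concept missing")
    if a.drug is None:
        violations.append("drug: required concept missing")
    if a.effect is None:
        violations.append("effect: required value missing")
    if a.cases is None or a.cases < 1:
        violations.append("cases: cases ≥ 1")
    if not a.source_bce:
        violations.append("source_bce: verbatim source text must be non-empty")
    if a.evidence_level == EvidenceLevel.CASE_REPORT and a.model != EvidenceModel.HUMAN_CLINICAL:
        violations.append("model: case report implies human/clinical")
    if a.stage is not None and not (1 <= a.stage <= 4):
        violations.append("stage: stage must be an integer 1–4")
    return violations


class IllegalTransition(ValueError):
    """Raised on a treatment-rationale status change outside the lifecycle."""


class TreatmentRationale:
    """A pro- or contra-recommendation explanation with its compiled
    assertions and lifecycle status.

    The controlled-English text is fixed at construction and cannot be
    reassigned afterwards: the verbatim source is the authoritative,
    lossless form of the rationale, and everything downstream (vetting,
    publication) refers back to it.
    """

    __slots__ = ("tr_id", "_bce_text", "polarity", "case_ref", "assertions", "_status")

    def __init__(
        self,
        tr_id: str,
        bce_text: str,
        polarity: Polarity = Polarity.PRO,
        case_ref: str = "",
        assertions: Optional[list[TTDAssertion]] = None,
        status: TRStatus = TRStatus.UNVETTED,
    ):
        if not bce_text:
            raise ValueError("bce_text must be non-empty")
        self.tr_id = tr_id
        object.__setattr__(self, "_bce_text", bce_text)
        self.polarity = Polarity(polarity)
        self.case_ref = case_ref
        self.assertions: list[TTDAssertion] = list(assertions or [])
        self._status = TRStatus(status)

    @property
    def bce_text(self) -> str:
        return self._bce_text

    @bce_text.setter
    def bce_text(self, value) -> None:  # pragma: no cover - guard
        raise AttributeError("bce_text is immutable after creation")

    @property
    def status(self) -> TRStatus:
        return self._status

    def transition(self, new_status: TRStatus) -> None:
        new_status = TRStatus(new_status)
        if (self._status, new_status) not in ALLOWED_TRANSITIONS:
            raise IllegalTransition(
                f"illegal status transition {self._status.value} -> {new_status.value}"
            )
        self._status = new_status

    def mark_vetted(self) -> None:
        self.transition(TRStatus.VETTED)

    def mark_rejected(self) -> None:
        self.transition(TRStatus.REJECTED)

    def mark_published(self) -> None:
        self.transition(TRStatus.PUBLISHED)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreatmentRationale({self.tr_id!r}, status={self._status.value})"


@dataclass
class CaseSummary:
    """De-identified summary of the patient case a rationale refers to."""

    case_id: str
    diagnosis: Optional[Concept] = None
    age: Optional[int] = None
    sex: Optional[str] = None
    stage: Optional[int] = None
    biomarkers: list[Concept] = field(default_factory=list)
    deidentified: bool = False


@dataclass(frozen=True)
class PatientProfile:
    """Molecular profile used for treatment ranking: a diagnosis concept
    plus the set of biomarker concepts observed in the tumor."""

    diagnosis: Concept
    biomarkers: frozenset[Concept] = frozenset()

    @property
    def biomarker_ids(self) -> frozenset[str]:
        return frozenset(b.concept_id for b in self.biomarkers)


# ---------------------------------------------------------------------------
# JSON Lines knowledge-base interchange
# ---------------------------------------------------------------------------

def write_kb(assertions: Iterable[TTDAssertion], path: Union[str, Path]) -> int:
    """Write assertions to a JSON Lines knowledge base; returns the count."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for a in assertions:
            fh.write(json.dumps(a.to_dict(), ensure_ascii=False) + "\n")
            n += 1
    return n


def read_kb(path: Union[str, Path]) -> list[TTDAssertion]:
    """Read a JSON Lines knowledge base written by :func:`write_kb`."""
    out: list[TTDAssertion] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TTDAssertion.from_dict(json.loads(line)))
    return out


def iter_kb_lines(assertions: Iterable[TTDAssertion]) -> Iterator[str]:
    for a in assertions:
        yield json.dumps(a.to_dict(), ensure_ascii=False)
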