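"""Treatment Explorer: evidence-weighted ranking of candidate drugs for
a patient's molecular profile.

An assertion matches a profile when its biomarker concept is among the
profile's biomarkers and its disease restriction (if any) equals the
profile's diagnosis — flat concept-id equality, no ontology traversal.

Each matching assertion contributes independently a weight

    w = L(evidence_level) × (1 + log10(cases))

where ``L`` is a configurable per-level multiplier (default 1..7 along
the ordinal evidence scale) and the case-count factor grows
logarithmically: a ten-fold larger series doubles the multiplier, and a
single-patient case report contributes exactly ``L(CASE_REPORT)``. A
drug's score is the sum of its sensitivity (pro) weights minus the sum
of its resistance (contra) weights; drugs are ranked by score, ties
broken alphabetically by preferred name. The independence assumption —
every assertion counts, even if several derive from the same source —
is a known limitation, kept deliberately simple here.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

from .core_model import (
    Concept,
    Effect,
    EvidenceLevel,
    PatientProfile,
    TTDAssertion,
    coerce_level,
)

#: Default per-level multipliers: the rank along the ordinal scale.
DEFAULT_LEVEL_WEIGHTS: Mapping[EvidenceLevel, float] = {
    level: float(level.value) for level in EvidenceLevel
}


def load_level_weights(path: Union[str, Path]) -> dict[EvidenceLevel, float]:
    """Level-weight table from a ``level\tweight`` TSV."""
    weights: dict[EvidenceLevel, float] = {}
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:2]] != ["level", "weight"]:
            raise ValueError(f"{path}: expected header 'level\\tweight'")
        for row in reader:
            if not row or not row[0].strip():
                continue
            weights[coerce_level(row[0].strip())] = float(row[1])
    return weights


def assertion_weight(
    a: TTDAssertion,
    weights: Optional[Mapping[EvidenceLevel, float]] = None,
) -> float:
    """Evidence weight of one assertion: ``L(level) × (1 + log10(cases))``."""
    table = DEFAULT_LEVEL_WEIGHTS if weights is None else weights
    level = coerce_level(a.evidence_level)
    if level not in table:
        raise ValueError(f"level {level.name} missing from weight table")
    if a.cases < 1:
        raise ValueError(f"cases must be ≥ 1, got {a.cases}")
    return table[level] * (1.0 + math.log10(a.cases))


def match_assertions(
    profile: PatientProfile, kb: Iterable[TTDAssertion]
) -> list[TTDAssertion]:
    """Assertions applicable to *profile*: biomarker in the profile's
    biomarker set, and disease either unrestricted or equal to the
    profile's diagnosis."""
    biomarker_ids = profile.biomarker_ids
    diagnosis_id = profile.diagnosis.concept_id
    return [
        a
        for a in kb
        if a.biomarker.concept_id in biomarker_ids
        and (a.disease is None or a.disease.concept_id == diagnosis_id)
    ]


@dataclass(frozen=True)
class RankedTreatment:
    """A candidate drug with its score and the full pro/contra evidence
    (assertion, weight) lists, each sorted by weight descending."""

    drug: Concept
    score: float
    pro: tuple[tuple[TTDAssertion, float], ...]
    contra: tuple[tuple[TTDAssertion, float], ...]


def _sorted_evidence(
    items: list[tuple[TTDAssertion, float]],
) -> tuple[tuple[TTDAssertion, float], ...]:
    return tuple(
        sorted(items, key=lambda aw: (-aw[1], aw[0].source_bce, aw[0].provenance_id))
    )


def rank_treatments(
    profile: PatientProfile,
    kb: Iterable[TTDAssertion],
    weights: Optional[Mapping[EvidenceLevel, float]] = None,
) -> list[RankedTreatment]:
    """Ranked treatments for *profile*: matched assertions grouped by
    drug, scored Σ(pro) − Σ(contra), sorted by score descending with
    alphabetical tie-break."""
    groups: dict[str, dict] = {}
    for a in match_assertions(profile, kb):
        w = assertion_weight(a, weights)
        g = groups.setdefault(
            a.drug.concept_id, {"drug": a.drug, "pro": [], "contra": []}
        )
        (g["pro"] if a.effect == Effect.SENSITIVITY else g["contra"]).append((a, w))
    ranked = [
        RankedTreatment(
            drug=g["drug"],
            score=sum(w for _, w in g["pro"]) - sum(w for _, w in g["contra"]),
            pro=_sorted_evidence(g["pro"]),
            contra=_sorted_evidence(g["contra"]),
        )
        for g in groups.values()
    ]
    ranked.sort(key=lambda r: (-r.score, r.drug.preferred_name, r.drug.concept_id))
    return ranked
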