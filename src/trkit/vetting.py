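"""Lightweight pre-publication review of treatment rationales.

Vetting is deliberately lighter than peer review: a rule-based
de-identification screen, per-vetter three-point Likert scores on four
dimensions (agreement, generality, importance, level of evidence), and
a configurable release decision. Scores are aggregated by median — the
scale is ordinal and a median is robust to a single outlying vetter.

The de-identification screen is a declared heuristic, not a compliance
certification: it flags calendar dates, long identifier-like digit runs
(MRN/SSN shapes), capitalized name bigrams after a personal title, and
ages of 90 or more (which narrow a patient enough to identify).
Clinical stage numbers, genomic coordinates and ages below 90 pass.
Dates inside citation-shaped parentheticals are masked before the date
rule runs: a literature citation is provenance, not patient data.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, asdict
from enum import Enum
from pathlib import Path
from typing import Union

import json

from .bce_parser import CITATION, tokenize

SCORE_DIMENSIONS = ("agreement", "generality", "importance", "evidence")
LIKERT_RANGE = (1, 2, 3)


class Decision(str, Enum):
    RELEASE = "RELEASE"
    HOLD = "HOLD"
    REJECT = "REJECT"


# ---------------------------------------------------------------------------
# De-identification screen
# ---------------------------------------------------------------------------

_MONTH = (
    r"(?:Jan(?:uary)?|Feb(?:ruary)?|Mar(?:ch)?|Apr(?:il)?|May|Jun(?:e)?|Jul(?:y)?|"
    r"Aug(?:ust)?|Sep(?:t(?:ember)?)?|Oct(?:ober)?|Nov(?:ember)?|Dec(?:ember)?)"
)

_DEID_RULES: list[tuple[str, re.Pattern]] = [
    ("calendar date", re.compile(rf"\b{_MONTH}\.?\s+\d{{1,2}}(?:\s*,\s*\d{{4}})?\b")),
    ("calendar date", re.compile(rf"\b\d{{1,2}}\s+{_MONTH}\.?(?:\s+\d{{4}})?\b")),
    ("calendar date", re.compile(r"\b\d{1,2}/\d{1,2}/\d{2,4}\b")),
    ("calendar date", re.compile(r"\b\d{4}-\d{2}-\d{2}\b")),
    ("identifier digit run", re.compile(r"\b\d{6,}\b")),
    (
        "titled personal name",
        re.compile(r"\b(?:Mr|Mrs|Ms|Dr|Prof)\.?\s+[A-Z][a-z]+(?:\s+[A-Z][a-z]+)?"),
    ),
]

_AGE_RE = re.compile(r"\b(\d{1,3})\s*(?:-|\s)?\s*year[- ]old\b", re.IGNORECASE)
_AGE_LIMIT = 90


@dataclass(frozen=True)
class DeidFlag:
    rule: str
    span: tuple[int, int]
    excerpt: str


@dataclass(frozen=True)
class DeidResult:
    ok: bool
    flags: tuple[DeidFlag, ...] = ()


def _mask_citations(text: str) -> str:
    """Blank out citation-shaped parentheticals, preserving offsets."""
    chars = list(text)
    for tok in tokenize(text):
        if tok.kind == CITATION:
            for i in range(*tok.span):
                chars[i] = " "
    return "".join(chars)


def deid_check(text: str) -> DeidResult:
    """Rule-based de-identification screen; pure and deterministic."""
    if not text:
        return DeidResult(True)
    masked = _mask_citations(text)
    flags: list[DeidFlag] = []
    for rule, pattern in _DEID_RULES:
        for m in pattern.finditer(masked):
            flags.append(DeidFlag(rule, m.span(), text[m.start() : m.end()]))
    for m in _AGE_RE.finditer(masked):
        if int(m.group(1)) >= _AGE_LIMIT:
            flags.append(DeidFlag(f"age ≥ {_AGE_LIMIT}", m.span(), m.group(0)))
    flags.sort(key=lambda f: f.span)
    return DeidResult(not flags, tuple(flags))


# ---------------------------------------------------------------------------
# Scores and release policy
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VettingRecord:
    """One vetter's review of one rationale: four 3-point Likert scores
    plus the outcome of the de-identification and encoding checks."""

    tr_id: str
    vetter_id: str
    agreement: int
    generality: int
    importance: int
    evidence: int
    bce_ok: bool = True
    deid_ok: bool = True

    def __post_init__(self):
        for dim in SCORE_DIMENSIONS:
            score = getattr(self, dim)
            if score not in LIKERT_RANGE:
                raise ValueError(f"{dim} score must be in {LIKERT_RANGE}, got {score}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VettingRecord":
        return cls(**{k: d[k] for k in (
            "tr_id", "vetter_id", "agreement", "generality", "importance",
            "evidence", "bce_ok", "deid_ok",
        )})


@dataclass(frozen=True)
class ReleasePolicy:
    """Local release standard: how many vetters, how much agreement, and
    whether de-identification must have passed for everyone."""

    quorum: int = 1
    min_agreement: int = 2
    require_deid: bool = True

    def __post_init__(self):
        if self.quorum < 1:
            raise ValueError("quorum must be ≥ 1")
        if self.min_agreement not in LIKERT_RANGE:
            raise ValueError(f"min_agreement must be in {LIKERT_RANGE}")


DEFAULT_POLICY = ReleasePolicy()


class VettingStore:
    """Per-(rationale, vetter) score records; resubmission replaces.

    The store also tracks which rationale ids it has ever been told
    about, so a decision can distinguish "no scores yet" (HOLD) from an
    id it has never seen (an error).
    """

    def __init__(self):
        self._records: dict[tuple[str, str], VettingRecord] = {}
        self._known: set[str] = set()

    def track(self, tr_id: str) -> None:
        self._known.add(tr_id)

    def record_score(self, tr, rec: VettingRecord) -> "VettingStore":
        """Append (or replace) *rec* for rationale *tr*.

        *tr* may be a TreatmentRationale (whose status must not be
        PUBLISHED — published records are immutable) or a bare tr_id.
        """
        tr_id = getattr(tr, "tr_id", tr)
        status = getattr(tr, "status", None)
        if status is not None and status.value in ("PUBLISHED",):
            raise ValueError(f"cannot score already-published rationale {tr_id}")
        if rec.tr_id != tr_id:
            raise ValueError(f"record tr_id {rec.tr_id!r} does not match {tr_id!r}")
        self._known.add(tr_id)
        self._records[(tr_id, rec.vetter_id)] = rec
        return self

    def records_for(self, tr_id: str) -> list[VettingRecord]:
        return [r for (tid, _), r in sorted(self._records.items()) if tid == tr_id]

    def __len__(self) -> int:
        return len(self._records)

    def release_decision(
        self, tr_id: str, policy: ReleasePolicy = DEFAULT_POLICY
    ) -> Decision:
        """HOLD below quorum; REJECT on median agreement of 1; RELEASE
        when quorum, median agreement and (if required) de-identification
        are all satisfied; otherwise HOLD."""
        if tr_id not in self._known:
            raise KeyError(f"unknown rationale id: {tr_id!r}")
        recs = self.records_for(tr_id)
        if len(recs) < policy.quorum:
            return Decision.HOLD
        med = statistics.median(r.agreement for r in recs)
        if med == 1:
            return Decision.REJECT
        if med >= policy.min_agreement and (
            not policy.require_deid or all(r.deid_ok for r in recs)
        ):
            return Decision.RELEASE
        return Decision.HOLD

    def summary(self, tr_id: str) -> dict:
        """Aggregate vetting summary published alongside a rationale;
        per-vetter detail stays local."""
        recs = self.records_for(tr_id)
        if not recs:
            return {"n_vetters": 0}
        out: dict = {"n_vetters": len(recs)}
        for dim in SCORE_DIMENSIONS:
            out[f"median_{dim}"] = statistics.median(getattr(r, dim) for r in recs)
        out["deid_ok"] = all(r.deid_ok for r in recs)
        out["bce_ok"] = all(r.bce_ok for r in recs)
        return out

    # -- persistence ---------------------------------------------------

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key in sorted(self._records):
                fh.write(json.dumps(self._records[key].to_dict(), ensure_ascii=False) + "\n")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "VettingStore":
        store = cls()
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rec = VettingRecord.from_dict(json.loads(line))
                    store._known.add(rec.tr_id)
                    store._records[(rec.tr_id, rec.vetter_id)] = rec
        return store


def load_policy(path: Union[str, Path]) -> ReleasePolicy:
    """Release policy from a small YAML config."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return ReleasePolicy(
        quorum=int(cfg.get("quorum", DEFAULT_POLICY.quorum)),
        min_agreement=int(cfg.get("min_agreement", DEFAULT_POLICY.min_agreement)),
        require_deid=bool(cfg.get("require_deid", DEFAULT_POLICY.require_deid)),
    )
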