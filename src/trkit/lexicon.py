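"""Pluggable concept dictionary with an open-vocabulary fallback.

A lexicon maps surface strings (case-insensitively) to concept bindings
drawn from a thesaurus-style code system. The bundled fixture
(``data/lexicon_synthetic.tsv``) is a small synthetic stand-in for a
full clinical thesaurus, covering the drugs, genes, alteration types,
diseases and trial-type phrases the shipped grammar and examples use; a
real thesaurus export loads through the same TSV interface.

Controlled biomedical English is conceptually open-ended — novel gene
fusions, diets, and non-technical observables will not be in any
thesaurus — so unknown terms never fail hard: :func:`fallback_tag`
assigns every non-empty string a rough part-of-speech from declared
suffix/shape heuristics, and the compiler mints stable ``LOCAL:<hash>``
concept ids for unlexiconed phrases so their assertions stay joinable.
"""

from __future__ import annotations

import csv
import hashlib
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

CATEGORIES = ("DRUG", "GENE", "ALTERATION", "DISEASE", "PROCEDURE", "FOOD", "OTHER")

#: Fallback part-of-speech tags, in the order tried.
FALLBACK_TAGS = ("NUMBER", "CITATION", "VERBISH", "MODIFIER", "NOUNISH", "UNKNOWN")

_VERB_SUFFIXES = ("ized", "izes", "ize", "ified", "ifies", "ify", "ated", "ating", "ates")
_MODIFIER_SUFFIXES = ("ly", "ive", "ous", "ful", "able", "ible")

_CITATION_SHAPE = re.compile(r"\((?:[^()]*)(?:(?:19|20)\d\d|\d+:\d+)(?:[^()]*)\)")


class LexiconError(ValueError):
    """Raised for malformed or internally inconsistent lexicon files."""


def _norm(term: str) -> str:
    return " ".join(term.replace("’", "'").lower().split())


@dataclass(frozen=True)
class ConceptBinding:
    """One surface form bound to a concept."""

    surface: str
    concept_id: str
    preferred_name: str
    category: str


class Lexicon:
    """Case-insensitive surface → concept dictionary.

    Multiple surfaces (synonyms) may share one concept id; a surface
    bound to two different concepts, or a concept id appearing under
    conflicting categories, is rejected at load time.
    """

    def __init__(self, bindings: Optional[list[ConceptBinding]] = None):
        self._by_surface: dict[str, ConceptBinding] = {}
        self._max_surface_words = 1
        for b in bindings or []:
            self.add(b)

    def add(self, binding: ConceptBinding) -> None:
        key = _norm(binding.surface)
        if not key:
            raise LexiconError("empty surface form")
        existing = self._by_surface.get(key)
        if existing is not None:
            if (existing.concept_id, existing.category) != (
                binding.concept_id,
                binding.category,
            ):
                raise LexiconError(
                    f"surface {binding.surface!r} bound to conflicting concepts "
                    f"{existing.concept_id}/{existing.category} vs "
                    f"{binding.concept_id}/{binding.category}"
                )
            return  # exact duplicate row: set semantics
        self._by_surface[key] = binding
        self._max_surface_words = max(self._max_surface_words, len(key.split()))

    def lookup(self, term: str) -> Optional[ConceptBinding]:
        """Exact, case-insensitive match on a surface form; ``None`` when
        absent. Multi-word surfaces are matched greedily longest-first by
        the caller (see :func:`trkit.bce_parser.lex_units`)."""
        if not term or not term.strip():
            raise ValueError("lookup term must be non-empty")
        return self._by_surface.get(_norm(term))

    def __contains__(self, term: str) -> bool:
        return bool(term.strip()) and _norm(term) in self._by_surface

    def __len__(self) -> int:
        return len(self._by_surface)

    def __iter__(self):
        return iter(self._by_surface.values())

    @property
    def max_surface_words(self) -> int:
        return self._max_surface_words

    def surfaces(self, category: Optional[str] = None) -> list[str]:
        """All loaded surface forms, optionally filtered by category,
        sorted for determinism."""
        return sorted(
            b.surface for b in self._by_surface.values()
            if category is None or b.category == category
        )


def load_lexicon(path: Union[str, Path]) -> Lexicon:
    """Load a lexicon from a TSV file with header
    ``surface  concept_id  preferred_name  category``."""
    lex = Lexicon()
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:4]] != [
            "surface",
            "concept_id",
            "preferred_name",
            "category",
        ]:
            raise LexiconError(
                f"{path}: expected header 'surface\\tconcept_id\\tpreferred_name\\tcategory'"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4 or any(not c.strip() for c in row[:4]):
                raise LexiconError(f"{path}: malformed row at line {lineno}: {row!r}")
            surface, concept_id, name, category = (c.strip() for c in row[:4])
            if category not in CATEGORIES:
                raise LexiconError(
                    f"{path}: unknown category {category!r} at line {lineno}"
                )
            try:
                lex.add(ConceptBinding(surface, concept_id, name, category))
            except LexiconError as exc:
                raise LexiconError(f"{path}: line {lineno}: {exc}") from None
    return lex


def fallback_tag(term: str) -> str:
    """Rough part-of-speech for a term not in the lexicon.

    Declared rules, in order: all-digit shape → NUMBER; parenthesized
    citation shape (contains a year or ``NN:NNN``) → CITATION; verb
    suffixes (-ize/-ized/-ated/...) → VERBISH; modifier suffixes
    (-ly/-ive/-ous/...) → MODIFIER; anything containing a letter or
    digit (including multi-word phrases) → NOUNISH; otherwise UNKNOWN.
    Total: never fails on a non-empty string.
    """
    if not term or not term.strip():
        raise ValueError("fallback_tag requires a non-empty term")
    t = term.strip()
    if t.replace(",", "").replace(".", "").isdigit() and any(c.isdigit() for c in t):
        return "NUMBER"
    if _CITATION_SHAPE.search(t):
        return "CITATION"
    words = t.split()
    if len(words) == 1:
        low = _norm(t)
        if any(low.endswith(s) for s in _VERB_SUFFIXES):
            return "VERBISH"
        if any(low.endswith(s) for s in _MODIFIER_SUFFIXES):
            return "MODIFIER"
    if any(c.isalnum() for c in t):
        return "NOUNISH"
    return "UNKNOWN"


def local_concept_id(phrase: str) -> str:
    """Stable content-hash concept id for an unlexiconed phrase."""
    digest = hashlib.sha256(_norm(phrase).encode("utf-8")).hexdigest()[:12]
    return f"LOCAL:{digest}"
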