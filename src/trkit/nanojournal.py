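"""A local, content-addressed pseudo-journal of published rationales,
in the style of nanopublication.

Each published record has three sections, mirroring the named-graph
structure of real nanopublications:

* **assertion** — the verbatim controlled-English text plus its compiled
  targeted-therapy assertions (the lossless source always travels with
  the compiled projection);
* **provenance** — the originating case/board reference, citation
  link-outs, and the aggregate vetting summary;
* **pubinfo** — journal metadata: timestamp, version, license, and an
  optional ``superseded_by`` backlink.

The record id is a SHA-256 hash of the canonical serialization (sorted
keys, UTF-8, no insignificant whitespace) of the assertion and
provenance sections, so identical content always gets the identical id
and any edit gets a new one. Content sections are immutable: a
correction is a *new* record, and the old record's ``superseded_by``
(journal metadata, outside the hash) points forward to it.

Storage is a local append-only directory of JSON files — one file per
record — deliberately kept off any live publication network. An
optional TriG export mirrors the three named graphs for linked-data
consumers.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

from .core_model import Effect, TRStatus, TTDAssertion, TreatmentRationale


class PublicationError(ValueError):
    """Raised when a rationale is not eligible for publication."""


def canonical_json(obj) -> str:
    """Canonical serialization: sorted keys, UTF-8, minimal whitespace."""
    return json.dumps(obj, sort_keys=True, separators=(",", ":"), ensure_ascii=False)


def content_id(assertion: dict, provenance: dict) -> str:
    payload = canonical_json(assertion) + "\n" + canonical_json(provenance)
    return "np-" + hashlib.sha256(payload.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class Nanopub:
    np_id: str
    assertion: dict
    provenance: dict
    pubinfo: dict

    def to_dict(self) -> dict:
        return {
            "np_id": self.np_id,
            "assertion": self.assertion,
            "provenance": self.provenance,
            "pubinfo": self.pubinfo,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Nanopub":
        return cls(d["np_id"], d["assertion"], d["provenance"], d["pubinfo"])

    @property
    def bce_text(self) -> str:
        return self.assertion["bce"]

    def iter_assertions(self) -> Iterable[TTDAssertion]:
        for a in self.assertion["assertions"]:
            yield TTDAssertion.from_dict(a)


class NanoJournal:
    """Append-only record store with content-hash identities.

    With a *root* directory, every record is persisted as
    ``<root>/<np_id>.json`` and reloaded on construction; without one
    the journal is in-memory.
    """

    def __init__(self, root: Optional[Union[str, Path]] = None):
        self.root = Path(root) if root is not None else None
        self._records: dict[str, Nanopub] = {}
        self._seq = 0
        if self.root is not None:
            self.root.mkdir(parents=True, exist_ok=True)
            for f in sorted(self.root.glob("np-*.json")):
                np = Nanopub.from_dict(json.loads(f.read_text(encoding="utf-8")))
                self._records[np.np_id] = np
            self._seq = len(self._records)

    def __len__(self) -> int:
        return len(self._records)

    def _persist(self, np: Nanopub) -> None:
        if self.root is not None:
            path = self.root / f"{np.np_id}.json"
            path.write_text(
                json.dumps(np.to_dict(), ensure_ascii=False, indent=1, sort_keys=True),
                encoding="utf-8",
            )

    # -- publication ---------------------------------------------------

    def publish(
        self,
        tr: TreatmentRationale,
        vet_summary: Optional[dict] = None,
        timestamp: Optional[str] = None,
    ) -> Nanopub:
        """Publish a vetted rationale; returns the (possibly pre-existing)
        immutable record and marks the rationale PUBLISHED.

        Unvetted rationales are refused: they have not entered the
        master knowledge base yet.
        """
        if tr.status != TRStatus.VETTED:
            raise PublicationError(
                f"rationale {tr.tr_id!r} is {tr.status.value}; only VETTED "
                "rationales can be published"
            )
        citations = sorted(
            {a.citation.url for a in tr.assertions if a.citation and a.citation.url}
        )
        if not tr.case_ref and not citations:
            raise PublicationError(
                f"rationale {tr.tr_id!r} has neither a case reference nor a "
                "citation; provenance must be non-empty"
            )
        assertion = {
            "bce": tr.bce_text,
            "polarity": tr.polarity.value,
            "assertions": [a.to_dict() for a in tr.assertions],
        }
        provenance = {
            "case_ref": tr.case_ref,
            "citations": citations,
            "vetting": dict(vet_summary or {}),
        }
        np_id = content_id(assertion, provenance)
        tr.mark_published()
        if np_id in self._records:
            return self._records[np_id]
        self._seq += 1
        if timestamp is None:
            from datetime import datetime, timezone

            timestamp = datetime.now(timezone.utc).isoformat()
        pubinfo = {
            "timestamp": timestamp,
            "sequence": self._seq,
            "version": 1,
            "superseded_by": None,
            "license": "CC-BY-4.0",
        }
        np = Nanopub(np_id, copy.deepcopy(assertion), copy.deepcopy(provenance), pubinfo)
        self._records[np_id] = np
        self._persist(np)
        return np

    def supersede(
        self,
        old_np_id: str,
        tr: TreatmentRationale,
        vet_summary: Optional[dict] = None,
        timestamp: Optional[str] = None,
    ) -> Nanopub:
        """Publish a corrected record and backlink the old one to it.

        Only journal metadata (pubinfo) of the old record changes; its
        content sections and id are untouched.
        """
        old = self.fetch(old_np_id)
        new = self.publish(tr, vet_summary, timestamp=timestamp)
        if new.np_id == old.np_id:
            raise PublicationError("correction is content-identical to the original")
        pubinfo = dict(old.pubinfo)
        pubinfo["superseded_by"] = new.np_id
        pubinfo["version"] = int(pubinfo.get("version", 1)) + 1
        updated = Nanopub(old.np_id, old.assertion, old.provenance, pubinfo)
        self._records[old.np_id] = updated
        self._persist(updated)
        return new

    # -- access --------------------------------------------------------

    def fetch(self, np_id: str) -> Nanopub:
        if np_id not in self._records:
            raise KeyError(f"unknown record id: {np_id!r}")
        np = self._records[np_id]
        # hand out copies so callers cannot mutate the stored record
        return Nanopub(
            np.np_id,
            copy.deepcopy(np.assertion),
            copy.deepcopy(np.provenance),
            copy.deepcopy(np.pubinfo),
        )

    def records(self) -> list[Nanopub]:
        """All records, ordered by (timestamp, sequence, np_id)."""
        return sorted(
            (self.fetch(k) for k in self._records),
            key=lambda np: (
                str(np.pubinfo.get("timestamp", "")),
                np.pubinfo.get("sequence", 0),
                np.np_id,
            ),
        )

    @staticmethod
    def _cid(value) -> Optional[str]:
        if value is None:
            return None
        return getattr(value, "concept_id", value)

    def query(
        self,
        drug=None,
        biomarker=None,
        disease=None,
        effect: Optional[Union[Effect, str]] = None,
    ) -> list[Nanopub]:
        """Records holding at least one assertion matching all given
        filters; matching is concept-id equality."""
        drug_id, biomarker_id, disease_id = (
            self._cid(drug),
            self._cid(biomarker),
            self._cid(disease),
        )
        effect_val = Effect(effect).value if effect is not None else None
        out = []
        for np in self.records():
            for a in np.assertion["assertions"]:
                if drug_id is not None and (a.get("drug") or {}).get("concept_id") != drug_id:
                    continue
                if (
                    biomarker_id is not None
                    and (a.get("biomarker") or {}).get("concept_id") != biomarker_id
                ):
                    continue
                if (
                    disease_id is not None
                    and (a.get("disease") or {}).get("concept_id") != disease_id
                ):
                    continue
                if effect_val is not None and a.get("effect") != effect_val:
                    continue
                out.append(np)
                break
        return out

    # -- knowledge-base export ----------------------------------------

    def export_kb(self) -> list[TTDAssertion]:
        """All assertions of current (non-superseded) records, in journal
        order — the knowledge base consumed by the treatment ranker."""
        kb: list[TTDAssertion] = []
        for np in self.records():
            if np.pubinfo.get("superseded_by"):
                continue
            kb.extend(np.iter_assertions())
        return kb

    def export_trig(self) -> str:
        """TriG rendering with assertion/provenance/pubinfo named graphs
        (requires the optional rdflib dependency)."""
        from rdflib import Dataset, Literal, Namespace, URIRef
        from rdflib.namespace import RDF

        NP = Namespace("http://example.org/np/")
        TR = Namespace("http://example.org/tr#")
        g = Dataset()
        for np in self.records():
            base = NP[np.np_id]
            head = g.graph(URIRef(base + "/assertion"))
            head.add((base, TR.bce, Literal(np.bce_text)))
            head.add((base, TR.polarity, Literal(np.assertion["polarity"])))
            for a in np.assertion["assertions"]:
                node = URIRef(base + "/assertion/" + (a["drug"] or {}).get("concept_id", "x"))
                head.add((node, RDF.type, TR.TTDAssertion))
                head.add((node, TR.json, Literal(canonical_json(a))))
            prov = g.graph(URIRef(base + "/provenance"))
            prov.add((base, TR.case_ref, Literal(np.provenance.get("case_ref", ""))))
            for url in np.provenance.get("citations", []):
                prov.add((base, TR.citation, URIRef(url)))
            pub = g.graph(URIRef(base + "/pubinfo"))
            pub.add((base, TR.timestamp, Literal(np.pubinfo.get("timestamp", ""))))
            pub.add((base, TR.license, Literal(np.pubinfo.get("license", ""))))
        return g.serialize(format="trig")
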