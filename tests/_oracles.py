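"""Independent oracles used by the test suite.

These deliberately re-derive expected results by the most naive route
available — exhaustive derivation enumeration for parsing, a flat
dictionary sum for ranking, an explicit truth table for release
decisions — and share no code with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import math


def _splits(i: int, j: int, k: int):
    """All ways to cut [i, j) into k non-empty adjacent intervals."""
    if k == 1:
        yield ((i, j),)
        return
    for mid in range(i + 1, j - k + 2):
        for rest in _splits(mid, j, k - 1):
            yield ((i, mid),) + rest


def enumerate_parses(tokens, rules, start):
    """All derivations of *tokens* (a list of terminal strings) from
    *start* under *rules* (a list of ``(lhs, rhs_tuple)``), as canonical
    nested tuples. A derivation that revisits a (symbol, span) already
    on its own ancestor path is cut, so the result is finite even for
    cyclic unit rules.
    """
    nonterms = {lhs for lhs, _ in rules}

    def derive(sym, i, j, path):
        if sym not in nonterms:
            # terminals (including never-defined symbols, which the open
            # grammar treats as terminals) match case-insensitively
            if j == i + 1 and tokens[i].lower() == sym.lower():
                return [("leaf", sym, tokens[i])]
            return []
        if (sym, i, j) in path:
            return []
        deeper = path | {(sym, i, j)}
        out = []
        for lhs, rhs in rules:
            if lhs != sym or len(rhs) > j - i:
                continue
            for bounds in _splits(i, j, len(rhs)):
                options = [derive(s, a, b, deeper) for s, (a, b) in zip(rhs, bounds)]
                if all(options):
                    for combo in itertools.product(*options):
                        out.append((sym, tuple(combo)))
        return out

    if not tokens:
        return set()
    return set(derive(start, 0, len(tokens), frozenset()))


def tree_to_tuple(tree):
    """Canonical nested-tuple form of an implementation parse tree."""
    from trkit.bce_parser import Leaf

    if isinstance(tree, Leaf):
        return ("leaf", tree.symbol, tree.unit.text)
    return (tree.symbol, tuple(tree_to_tuple(c) for c in tree.children))


def brute_force_ranking(profile, kb, level_weights):
    """Flat re-summation of the ranking score, independent of the
    grouping/sorting machinery: returns [(drug_id, drug_name, score)]
    sorted by score desc then name."""
    profile_markers = {b.concept_id for b in profile.biomarkers}
    scores: dict[str, float] = {}
    names: dict[str, str] = {}
    for a in kb:
        if a.biomarker.concept_id not in profile_markers:
            continue
        if a.disease is not None and a.disease.concept_id != profile.diagnosis.concept_id:
            continue
        w = level_weights[a.evidence_level] * (1 + math.log10(a.cases))
        sign = 1.0 if a.effect.value == "SENSITIVITY" else -1.0
        scores[a.drug.concept_id] = scores.get(a.drug.concept_id, 0.0) + sign * w
        names[a.drug.concept_id] = a.drug.preferred_name
    return sorted(
        ((cid, names[cid], s) for cid, s in scores.items()),
        key=lambda t: (-t[2], t[1], t[0]),
    )


def release_truth_table(agreement, deid_ok, min_agreement=2):
    """Expected single-vetter (quorum 1) decision, written out directly."""
    if agreement == 1:
        return "REJECT"
    if agreement >= min_agreement and deid_ok:
        return "RELEASE"
    return "HOLD"
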