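"""Tokenizer and bottom-up chart parser for controlled biomedical English.

The parsing strategy is deliberately minimal: an agenda-driven,
bottom-up *extension* chart parser over a plain-text context-free
grammar. Complete constituents are packed into a shared forest keyed by
(symbol, span); partial edges extend whenever a constituent they expect
appears adjacent to them. Packing plus edge deduplication keeps the
chart finite even under cyclic unit rules (``A -> B``, ``B -> A``);
tree extraction cuts any derivation that revisits a (symbol, span)
already on its ancestor path, so the set of returned parses is finite.

Open vocabulary is handled at the lexical level: a token bound to a
lexicon concept matches the corresponding ``@CATEGORY`` slot directly,
while an unknown noun-ish token matches the slot at a *fallback* cost.
Parses are returned fewest-fallbacks-first, then in a deterministic
lexicographic derivation order, so downstream consumers can simply take
the first parse.

Tokenization is lossless: every token records its character span in the
source, and :func:`detokenize` reproduces the input byte-for-byte.
"""

from __future__ import annotations

import itertools
import re
import warnings
from collections import defaultdict, deque
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .lexicon import ConceptBinding, Lexicon, fallback_tag

# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

WORD = "WORD"
NUMBER = "NUMBER"
PUNCT = "PUNCT"
CITATION = "CITATION"


@dataclass(frozen=True)
class Token:
    text: str
    span: tuple[int, int]  # 0-based, half-open character offsets
    kind: str


# a parenthesized span is a citation if it contains a year or a
# journal-style volume:page reference like "16:568"
_CITATION_BODY = re.compile(r"(?:19|20)\d\d|\d+:\d+")
_WORD_RE = re.compile(r"[0-9A-Za-z](?:[0-9A-Za-z'’-]*[0-9A-Za-z])?")


def tokenize(text: str) -> list[Token]:
    """Split text into WORD / NUMBER / PUNCT / CITATION tokens.

    Rules, in order: a parenthesized span matching a citation shape
    becomes a single CITATION token; maximal alphanumeric runs with
    internal hyphens/apostrophes stay one WORD (gene fusions like
    ``EIF2AK3-alk``, possessives like ``male's``); all-digit runs are
    NUMBER; any other non-space character is its own PUNCT token.
    """
    tokens: list[Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch == "(":
            close = text.find(")", i)
            if close != -1 and _CITATION_BODY.search(text[i : close + 1]):
                tokens.append(Token(text[i : close + 1], (i, close + 1), CITATION))
                i = close + 1
                continue
        m = _WORD_RE.match(text, i)
        if m:
            t = m.group(0)
            tokens.append(Token(t, (i, m.end()), NUMBER if t.isdigit() else WORD))
            i = m.end()
            continue
        tokens.append(Token(ch, (i, i + 1), PUNCT))
        i += 1
    return tokens


def detokenize(text: str, tokens: Sequence[Token]) -> str:
    """Reconstruct the source from tokens plus the original inter-token
    separators; byte-identical to *text* for tokens from :func:`tokenize`."""
    parts: list[str] = []
    pos = 0
    for tok in tokens:
        s, e = tok.span
        if s < pos or text[s:e] != tok.text:
            raise ValueError(f"token {tok!r} does not tile the source text")
        parts.append(text[pos:s])
        parts.append(tok.text)
        pos = e
    parts.append(text[pos:])
    return "".join(parts)


# ---------------------------------------------------------------------------
# Grammar
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrammarRule:
    lhs: str
    rhs: tuple[str, ...]

    def __post_init__(self):
        if not self.rhs:
            raise ValueError("grammar rule rhs must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.lhs} -> {' '.join(self.rhs)}"


class Grammar:
    def __init__(self, rules: Sequence[GrammarRule], start: Optional[str] = None):
        if not rules:
            raise ValueError("grammar needs at least one rule")
        self.rules: list[GrammarRule] = list(rules)
        self.start: str = start if start is not None else self.rules[0].lhs
        self.nonterminals: frozenset[str] = frozenset(r.lhs for r in self.rules)
        self.rules_for: dict[str, list[GrammarRule]] = defaultdict(list)
        for r in self.rules:
            self.rules_for[r.lhs].append(r)

    def __len__(self) -> int:
        return len(self.rules)


_UPPER_SYM = re.compile(r"^[A-Z][A-Z0-9_]*$")


def parse_grammar(text: str, start: Optional[str] = None) -> Grammar:
    """Parse ``LHS -> sym sym ...`` rules, one per line; ``#`` comments."""
    rules: list[GrammarRule] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise ValueError(f"line {lineno}: expected 'LHS -> sym ...': {raw!r}")
        lhs, rhs_text = line.split("->", 1)
        lhs = lhs.strip()
        rhs = tuple(rhs_text.split())
        if not lhs or not rhs:
            raise ValueError(f"line {lineno}: empty lhs or rhs: {raw!r}")
        rules.append(GrammarRule(lhs, rhs))
    grammar = Grammar(rules, start=start)
    # An ALL-CAPS rhs symbol that is never defined is probably a missing
    # rule; warn but keep the grammar open-ended.
    for r in rules:
        for sym in r.rhs:
            if (
                _UPPER_SYM.match(sym)
                and sym not in grammar.nonterminals
                and not sym.startswith(("@", "%"))
            ):
                warnings.warn(
                    f"symbol {sym!r} in rule '{r}' is never defined", stacklevel=2
                )
    return grammar


def load_grammar(path: Union[str, Path], start: Optional[str] = None) -> Grammar:
    return parse_grammar(Path(path).read_text(encoding="utf-8"), start=start)


# ---------------------------------------------------------------------------
# Lexical units: tokens + concept bindings / fallback tags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LexicalUnit:
    """One or more adjacent tokens treated as a single parse leaf."""

    tokens: tuple[Token, ...]
    text: str
    kind: str
    binding: Optional[ConceptBinding] = None
    tag: Optional[str] = None

    @property
    def span(self) -> tuple[int, int]:
        return (self.tokens[0].span[0], self.tokens[-1].span[1])


def lex_units(
    tokens: Sequence[Token], lexicon: Optional[Lexicon] = None
) -> tuple[LexicalUnit, ...]:
    """Attach concept bindings, merging multi-word lexicon surfaces
    greedily longest-first into single units.

    OTHER-category surfaces are never merged: phrases like trial types
    are consumed word-by-word by the grammar's terminals, and merging
    them would hide those words from terminal matching.
    """
    units: list[LexicalUnit] = []
    i, n = 0, len(tokens)
    max_words = lexicon.max_surface_words if lexicon else 1
    while i < n:
        tok = tokens[i]
        if lexicon is not None and tok.kind in (WORD, NUMBER):
            merged = None
            for length in range(min(max_words, n - i), 1, -1):
                window = tokens[i : i + length]
                if any(t.kind not in (WORD, NUMBER) for t in window):
                    continue
                candidate = " ".join(t.text for t in window)
                b = lexicon.lookup(candidate)
                if b is not None and b.category != "OTHER":
                    merged = LexicalUnit(tuple(window), candidate, WORD, binding=b)
                    i += length
                    break
            if merged is not None:
                units.append(merged)
                continue
        binding = None
        if lexicon is not None and tok.kind in (WORD, NUMBER):
            binding = lexicon.lookup(tok.text)
        tag = None
        if binding is None and tok.kind == WORD:
            tag = fallback_tag(tok.text)
        units.append(LexicalUnit((tok,), tok.text, tok.kind, binding=binding, tag=tag))
        i += 1
    return tuple(units)


# ---------------------------------------------------------------------------
# Parse trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Leaf:
    """A terminal in a parse tree: the rhs symbol it satisfied plus the
    lexical unit that satisfied it."""

    symbol: str
    unit: LexicalUnit
    fallback_used: bool = False

    @property
    def n_fallbacks(self) -> int:
        return int(self.fallback_used)

    def to_dict(self) -> dict:
        d: dict = {"symbol": self.symbol, "text": self.unit.text, "span": list(self.unit.span)}
        if self.unit.binding is not None:
            d["binding"] = {
                "concept_id": self.unit.binding.concept_id,
                "preferred_name": self.unit.binding.preferred_name,
                "category": self.unit.binding.category,
            }
        elif self.unit.tag is not None:
            d["tag"] = self.unit.tag
        if self.fallback_used:
            d["fallback"] = True
        return d


@dataclass(frozen=True)
class ParseTree:
    symbol: str
    children: tuple[Union["ParseTree", Leaf], ...]

    @property
    def leaves(self) -> tuple[Leaf, ...]:
        out: list[Leaf] = []
        stack: list[Union[ParseTree, Leaf]] = [self]
        while stack:
            node = stack.pop()
            if isinstance(node, Leaf):
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return tuple(out)

    @property
    def n_fallbacks(self) -> int:
        return sum(leaf.fallback_used for leaf in self.leaves)

    @property
    def span(self) -> tuple[int, int]:
        leaves = self.leaves
        return (leaves[0].unit.span[0], leaves[-1].unit.span[1])

    def derivation_key(self) -> str:
        """Canonical preorder string; the deterministic tie-break order."""
        if all(isinstance(c, Leaf) for c in self.children):
            body = " ".join(f"{c.symbol}={c.unit.text}" for c in self.children)
        else:
            body = " ".join(
                c.derivation_key() if isinstance(c, ParseTree) else f"{c.symbol}={c.unit.text}"
                for c in self.children
            )
        return f"({self.symbol} {body})"

    def to_dict(self) -> dict:
        return {
            "symbol": self.symbol,
            "children": [c.to_dict() for c in self.children],
        }

    def find_all(self, symbol: str) -> list["ParseTree"]:
        """All subtrees labelled *symbol*, in left-to-right preorder."""
        found: list[ParseTree] = []
        stack: list[ParseTree] = [self]
        while stack:
            node = stack.pop(0)
            if node.symbol == symbol:
                found.append(node)
            stack = [c for c in node.children if isinstance(c, ParseTree)] + stack
        return found

    def find_leaves(self, symbol: str) -> list[Leaf]:
        return [leaf for leaf in self.leaves if leaf.symbol == symbol]


# ---------------------------------------------------------------------------
# The chart parser proper
# ---------------------------------------------------------------------------


def _match_symbol(sym: str, unit: LexicalUnit, nonterminals: frozenset[str]):
    """Can *sym* be satisfied lexically by *unit*?

    Returns ``None`` for no match, else a bool: was a fallback used?
    """
    if sym in nonterminals:
        return None
    if sym == "%NUMBER":
        return False if unit.kind == NUMBER else None
    if sym == "%CITATION":
        return False if unit.kind == CITATION else None
    if sym.startswith("@"):
        category = sym[1:]
        if unit.binding is not None and unit.binding.category == category:
            return False
        if unit.binding is None and unit.kind == WORD and unit.tag == "NOUNISH":
            return True
        return None
    # plain terminal: case-insensitive surface match (typographic
    # apostrophes normalized)
    norm = unit.text.replace("’", "'").lower()
    return False if norm == sym.replace("’", "'").lower() else None


def parse_units(
    units: Sequence[LexicalUnit], grammar: Grammar, max_trees: Optional[int] = None
) -> list[ParseTree]:
    """All complete parses of *units* under *grammar*, ordered by
    (n_fallbacks, derivation key). Empty list when there is no parse."""
    n = len(units)
    if n == 0:
        return []
    nonterminals = grammar.nonterminals
    lexical_syms = {s for r in grammar.rules for s in r.rhs if s not in nonterminals}
    rules_by_first: dict[str, list[GrammarRule]] = defaultdict(list)
    for r in grammar.rules:
        rules_by_first[r.rhs[0]].append(r)

    # packed forest: (sym, i, j) -> list of alternatives
    #   alt = ("leaf", unit_index, fallback_used) | ("rule", rule, child_keys)
    node_alts: dict[tuple, list[tuple]] = {}
    alt_seen: set[tuple] = set()
    nodes_at: dict[tuple, list[tuple]] = defaultdict(list)  # (sym, start) -> keys
    expecting: dict[tuple, list[tuple]] = defaultdict(list)  # (sym, pos) -> edges
    edges_seen: set[tuple] = set()
    tasks: deque[tuple] = deque()

    def push_alt(key: tuple, alt: tuple) -> None:
        if (key, alt) in alt_seen:
            return
        alt_seen.add((key, alt))
        if key not in node_alts:
            node_alts[key] = [alt]
            tasks.append(("node", key))
        else:
            node_alts[key].append(alt)

    def push_edge(rule: GrammarRule, dot: int, start: int, end: int, children: tuple) -> None:
        e = (rule, dot, start, end, children)
        if e in edges_seen:
            return
        edges_seen.add(e)
        tasks.append(("edge", e))

    # lexical pass: one leaf node per matching symbol form per unit
    for idx, unit in enumerate(units):
        for sym in lexical_syms:
            m = _match_symbol(sym, unit, nonterminals)
            if m is not None:
                push_alt((sym, idx, idx + 1), ("leaf", idx, m))

    while tasks:
        kind, item = tasks.popleft()
        if kind == "node":
            sym, i, j = item
            nodes_at[(sym, i)].append(item)
            # bottom-up rule invocation: any rule starting with this symbol
            for rule in rules_by_first.get(sym, ()):
                push_edge(rule, 1, i, j, (item,))
            # extend partial edges that were waiting for this symbol here
            for rule, dot, start, _end, children in list(expecting.get((sym, i), ())):
                push_edge(rule, dot + 1, start, j, children + (item,))
        else:
            rule, dot, start, end, children = item
            if dot == len(rule.rhs):
                push_alt((rule.lhs, start, end), ("rule", rule, children))
            else:
                nxt = rule.rhs[dot]
                expecting[(nxt, end)].append(item)
                for key in list(nodes_at.get((nxt, end), ())):
                    push_edge(rule, dot + 1, start, key[2], children + (key,))

    root_key = (grammar.start, 0, n)
    if root_key not in node_alts:
        return []

    def extract(key: tuple, on_path: frozenset) -> list[Union[ParseTree, Leaf]]:
        results: list[Union[ParseTree, Leaf]] = []
        blocked = on_path | {key}
        for alt in node_alts[key]:
            if alt[0] == "leaf":
                _, idx, fb = alt
                results.append(Leaf(key[0], units[idx], fb))
            else:
                _, rule, child_keys = alt
                if any(ck in blocked for ck in child_keys):
                    continue  # cycle through a (symbol, span) already on the path
                child_options = [extract(ck, blocked) for ck in child_keys]
                if any(not opts for opts in child_options):
                    continue
                for combo in itertools.product(*child_options):
                    results.append(ParseTree(rule.lhs, tuple(combo)))
        return results

    trees = [t for t in extract(root_key, frozenset()) if isinstance(t, ParseTree)]
    trees.sort(key=lambda t: (t.n_fallbacks, t.derivation_key()))
    if max_trees is not None:
        trees = trees[:max_trees]
    return trees


def parse(
    tokens: Sequence[Token],
    grammar: Grammar,
    lexicon: Optional[Lexicon] = None,
    max_trees: Optional[int] = None,
) -> list[ParseTree]:
    """Tokenized text → all complete parses (see :func:`parse_units`)."""
    return parse_units(lex_units(tokens, lexicon), grammar, max_trees=max_trees)


def parse_text(
    text: str,
    grammar: Grammar,
    lexicon: Optional[Lexicon] = None,
    max_trees: Optional[int] = None,
) -> list[ParseTree]:
    return parse(tokenize(text), grammar, lexicon=lexicon, max_trees=max_trees)
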