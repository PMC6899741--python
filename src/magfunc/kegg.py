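"""KEGG module definition logic and module completion scoring.

A KEGG metabolic module is defined by a boolean-style expression over KEGG
Orthology (KO) identifiers.  The expression grammar follows the public KEGG
DEFINITION conventions:

* space   — serial reaction steps (an AND over steps);
* ``,``   — alternative enzymes/combinations for one slot (OR);
* ``+``   — subunits of one enzyme complex (AND, binds tighter than ``,``);
* ``-X``  — optional, non-essential component (excluded from scoring);
* ``--``  — an unspecified/unspecifiable component (always counted present);
* parentheses for grouping.

Operator precedence, tightest to loosest: ``+``/``-`` then ``,`` then space.

The module completion score (MCS) of a genome's KO set against a parsed
definition lies in [0, 1]: each top-level step scores the *proportion* of the
orthologs it requires that the genome possesses, alternatives score as the
best (max) alternative — any sufficient combination completes the slot — and
the MCS is the arithmetic mean of the step scores.  1 means the pathway is
fully encoded, 0 means it is absent.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DefinitionParseError, ValidationError

__all__ = [
    "Atom",
    "And",
    "Or",
    "Optional",
    "Wildcard",
    "ModuleDefinition",
    "KOAnnotationTable",
    "MCSMatrix",
    "parse_module_definition",
    "serialize_expression",
    "node_completeness",
    "module_completion_score",
    "compute_mcs_matrix",
]

KO_PATTERN = re.compile(r"^K\d{5}$")


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Atom:
    """A single KO requirement (``K#####``)."""

    ko: str
    kind = "ATOM"

    def __post_init__(self):
        if not KO_PATTERN.match(self.ko):
            raise ValueError(f"invalid KO identifier: {self.ko!r}")


@dataclass(frozen=True)
class Wildcard:
    """``--``: an unspecified component, always scored as present."""

    kind = "WILDCARD"


@dataclass(frozen=True)
class Optional:
    """A non-essential component; never contributes to a score."""

    child: "Node"
    kind = "OPTIONAL"


@dataclass(frozen=True)
class And:
    """Conjunction.  ``op`` records the surface operator: ' ' for serial
    steps, '+' for complex subunits.  Scoring is identical (mean); the flag
    only controls serialization and top-level step splitting."""

    children: tuple
    op: str = " "
    kind = "AND"

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("AND nodes need >= 2 children")


@dataclass(frozen=True)
class Or:
    """Disjunction: alternative enzymes or combinations for one slot."""

    children: tuple
    kind = "OR"

    def __post_init__(self):
        if len(self.children) < 2:
            raise ValueError("OR nodes need >= 2 children")


Node = Atom | Wildcard | Optional | And | Or


@dataclass(frozen=True)
class ModuleDefinition:
    """A parsed metabolic module."""

    module_id: str
    root: Node
    name: str = ""
    source_text: str = ""

    @property
    def steps(self) -> tuple:
        """Top-level reaction steps (space-separated units only)."""
        if isinstance(self.root, And) and self.root.op == " ":
            return self.root.children
        return (self.root,)

    def kos(self) -> set[str]:
        """All KO ids appearing anywhere in the definition."""
        out: set[str] = set()
        _collect_kos(self.root, out)
        return out

    def has_wildcard(self) -> bool:
        return _has_wildcard(self.root)


def _collect_kos(node: Node, out: set[str]) -> None:
    if isinstance(node, Atom):
        out.add(node.ko)
    elif isinstance(node, Optional):
        _collect_kos(node.child, out)
    elif isinstance(node, (And, Or)):
        for c in node.children:
            _collect_kos(c, out)


def _has_wildcard(node: Node) -> bool:
    if isinstance(node, Wildcard):
        return True
    if isinstance(node, Optional):
        return _has_wildcard(node.child)
    if isinstance(node, (And, Or)):
        return any(_has_wildcard(c) for c in node.children)
    return False


# ---------------------------------------------------------------------------
# Parser (recursive descent over a small token stream)
# ---------------------------------------------------------------------------

_TOK_KO = "KO"
_TOK_SP = "SP"
_TOK_COMMA = ","
_TOK_PLUS = "+"
_TOK_MINUS = "-"
_TOK_WILD = "--"
_TOK_LP = "("
_TOK_RP = ")"


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == " ":
            j = i
            while i < n and text[i] == " ":
                i += 1
            tokens.append((_TOK_SP, " ", j))
        elif c == "(":
            tokens.append((_TOK_LP, c, i)); i += 1
        elif c == ")":
            tokens.append((_TOK_RP, c, i)); i += 1
        elif c == ",":
            tokens.append((_TOK_COMMA, c, i)); i += 1
        elif c == "+":
            tokens.append((_TOK_PLUS, c, i)); i += 1
        elif c == "-":
            if i + 1 < n and text[i + 1] == "-":
                tokens.append((_TOK_WILD, "--", i)); i += 2
            else:
                tokens.append((_TOK_MINUS, c, i)); i += 1
        elif c in "Kk":
            m = re.match(r"[Kk]\d{5}(?![0-9A-Za-z])", text[i:])
            if not m:
                raise DefinitionParseError(
                    f"malformed KO token starting at {text[i:i+7]!r}", i)
            tokens.append((_TOK_KO, m.group(0).upper(), i))
            i += m.end()
        else:
            raise DefinitionParseError(f"unexpected character {c!r}", i)
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise DefinitionParseError("unexpected end of definition", len(self.text))
        self.pos += 1
        return tok

    # sequence := alternatives (SP alternatives)*
    def parse_sequence(self) -> Node:
        items = [self.parse_alternatives()]
        while True:
            tok = self._peek()
            if tok is None or tok[0] != _TOK_SP:
                break
            self._next()
            if self._peek() is None or self._peek()[0] == _TOK_RP:
                break  # tolerate trailing space
            items.append(self.parse_alternatives())
        return items[0] if len(items) == 1 else And(tuple(items), op=" ")

    # alternatives := complex (',' complex)*
    def parse_alternatives(self) -> Node:
        parts = [self.parse_complex()]
        while self._peek() is not None and self._peek()[0] == _TOK_COMMA:
            self._next()
            parts.append(self.parse_complex())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    # complex := ['-'] unit (('+'|'-') unit)*
    def parse_complex(self) -> Node:
        parts: list[Node] = []
        tok = self._peek()
        if tok is not None and tok[0] == _TOK_MINUS:
            self._next()
            parts.append(Optional(self.parse_unit()))
        else:
            parts.append(self.parse_unit())
        while self._peek() is not None and self._peek()[0] in (_TOK_PLUS, _TOK_MINUS):
            kind, _, _ = self._next()
            unit = self.parse_unit()
            parts.append(Optional(unit) if kind == _TOK_MINUS else unit)
        return parts[0] if len(parts) == 1 else And(tuple(parts), op="+")

    # unit := KO | '--' | '(' sequence ')'
    def parse_unit(self) -> Node:
        kind, value, offset = self._next()
        if kind == _TOK_KO:
            return Atom(value)
        if kind == _TOK_WILD:
            return Wildcard()
        if kind == _TOK_LP:
            inner = self.parse_sequence()
            tok = self._peek()
            if tok is None or tok[0] != _TOK_RP:
                raise DefinitionParseError(
                    "unbalanced parenthesis opened", offset)
            self._next()
            return inner
        raise DefinitionParseError(f"unexpected token {value!r}", offset)


def parse_module_definition(module_id: str, definition: str,
                            name: str = "") -> ModuleDefinition:
    """Parse a KEGG-style DEFINITION string into a :class:`ModuleDefinition`.

    Raises
    ------
    DefinitionParseError
        On empty input, malformed KO tokens, or unbalanced parentheses; the
        error carries the character offset of the problem.
    """
    text = definition.strip()
    if not text:
        raise DefinitionParseError("empty module definition", 0)
    parser = _Parser(text)
    root = parser.parse_sequence()
    if parser.pos != len(parser.tokens):
        kind, value, offset = parser.tokens[parser.pos]
        raise DefinitionParseError(f"unexpected token {value!r}", offset)
    return ModuleDefinition(module_id=module_id, root=root, name=name,
                            source_text=definition)


# ---------------------------------------------------------------------------
# Serialization (canonical round-trip)
# ---------------------------------------------------------------------------

# precedence context levels: 0 = sequence, 1 = alternatives, 2 = complex, 3 = unit
def _serialize(node: Node, level: int) -> str:
    if isinstance(node, Atom):
        return node.ko
    if isinstance(node, Wildcard):
        return "--"
    if isinstance(node, Optional):
        return "-" + _opt_body(node.child)
    if isinstance(node, Or):
        s = ",".join(_serialize(c, 2) for c in node.children)
        return f"({s})" if level > 1 else s
    if isinstance(node, And) and node.op == "+":
        parts = []
        for i, c in enumerate(node.children):
            if isinstance(c, Optional):
                parts.append("-" + _opt_body(c.child))
            else:
                parts.append(("+" if i else "") + _serialize(c, 3))
        s = "".join(parts)
        return f"({s})" if level > 2 else s
    if isinstance(node, And):  # op == " "
        s = " ".join(_serialize(c, 1) for c in node.children)
        return f"({s})" if level > 0 else s
    raise TypeError(f"unknown node {node!r}")


def _opt_body(child: Node) -> str:
    """Body of an optional marker; parenthesized when it would start with
    '-' (e.g. a wildcard), which would otherwise read as the '--' token."""
    s = _serialize(child, 3)
    return f"({s})" if s.startswith("-") else s


def serialize_expression(node: Node) -> str:
    """Render an expression tree back to canonical DEFINITION syntax."""
    return _serialize(node, 0)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _score(node: Node, kos: frozenset) -> float | None:
    """Recursive completeness; ``None`` marks zero-weight (optional-only)
    nodes that are excluded from their parent's aggregate."""
    if isinstance(node, Atom):
        return 1.0 if node.ko in kos else 0.0
    if isinstance(node, Wildcard):
        return 1.0
    if isinstance(node, Optional):
        return None
    if isinstance(node, And):
        scores = [s for c in node.children if (s := _score(c, kos)) is not None]
        return float(np.mean(scores)) if scores else None
    if isinstance(node, Or):
        scores = [s for c in node.children if (s := _score(c, kos)) is not None]
        return max(scores) if scores else None
    raise TypeError(f"unknown node {node!r}")


def node_completeness(node: Node, kos: Iterable[str]) -> float:
    """Completeness of one expression node against a KO set, in [0, 1].

    ATOM scores 1/0 on membership; AND scores the mean of its (non-optional)
    children — fractional credit for partially present combinations; OR
    scores the best alternative; ``--`` scores 1.  An OPTIONAL node scores
    as its wrapped child (parents exclude optionals from their own mean).
    """
    koset = frozenset(k.upper() for k in kos)
    target = node.child if isinstance(node, Optional) else node
    s = _score(target, koset)
    return 0.0 if s is None else float(s)


def module_completion_score(module: ModuleDefinition, kos: Iterable[str]) -> float:
    """Module completion score: mean over top-level steps of step completeness.

    Optional-only steps carry no weight and are excluded from the mean.
    """
    koset = frozenset(k.upper() for k in kos)
    scores = [s for step in module.steps if (s := _score(step, koset)) is not None]
    return float(np.mean(scores)) if scores else 0.0


# ---------------------------------------------------------------------------
# Annotation tables and MCS matrices
# ---------------------------------------------------------------------------

@dataclass
class KOAnnotationTable:
    """ORF-level KO annotations: one row per (orf_id, mag_id, ko_id)."""

    df: pd.DataFrame  # columns: orf_id, mag_id, ko_id

    REQUIRED = ("orf_id", "mag_id", "ko_id")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation table missing columns: {missing}")
        self.df = self.df.copy()
        self.df["ko_id"] = self.df["ko_id"].str.upper()
        bad = self.df.loc[~self.df["ko_id"].str.match(KO_PATTERN), "ko_id"]
        if len(bad):
            raise ValidationError(
                f"invalid KO identifiers in annotation table: {sorted(set(bad))[:5]}")

    def mag_ko_sets(self) -> dict[str, set[str]]:
        """Union of KO annotations over all ORFs of each MAG."""
        return {mag: set(sub["ko_id"]) for mag, sub in self.df.groupby("mag_id")}

    def mag_ids(self) -> list[str]:
        return sorted(self.df["mag_id"].unique())


@dataclass
class MCSMatrix:
    """MAG x module completion scores, dense, entries in [0, 1]."""

    df: pd.DataFrame  # index: mag ids, columns: module ids

    def __post_init__(self):
        vals = self.df.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or vals.min() < 0 or vals.max() > 1):
            raise ValidationError("MCS matrix entries must be finite and in [0, 1]")

    @property
    def mags(self) -> list[str]:
        return list(self.df.index)

    @property
    def modules(self) -> list[str]:
        return list(self.df.columns)


def compute_mcs_matrix(annotations: KOAnnotationTable,
                       modules: Sequence[ModuleDefinition],
                       mag_ids: Sequence[str] | None = None) -> MCSMatrix:
    """Score every MAG's KO set against every module.

    A MAG's KO set is the union of annotations across all of its ORFs.
    Modules absent from a MAG score 0, never missing.  If ``mag_ids`` is
    given, annotation rows referencing MAGs outside that list raise
    :class:`ValidationError` (listing the offending ids), and listed MAGs
    with no annotations get all-zero rows.
    """
    if not modules:
        raise ValidationError("module list is empty")
    ko_sets = annotations.mag_ko_sets()
    if mag_ids is None:
        mag_ids = sorted(ko_sets)
    else:
        unknown = sorted(set(ko_sets) - set(mag_ids))
        if unknown:
            raise ValidationError(
                f"annotation rows reference unknown MAG ids: {unknown}")
    data = np.zeros((len(mag_ids), len(modules)))
    for i, mag in enumerate(mag_ids):
        kos = frozenset(ko_sets.get(mag, set()))
        for j, mod in enumerate(modules):
            data[i, j] = module_completion_score(mod, kos)
    df = pd.DataFrame(data, index=list(mag_ids),
                      columns=[m.module_id for m in modules])
    return MCSMatrix(df)
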