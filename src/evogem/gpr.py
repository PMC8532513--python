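"""Gene-protein-reaction (GPR) boolean logic.

A GPR rule gates a reaction's availability in a species by the presence of
ortholog groups: ``and`` joins subunits of an enzyme complex, ``or`` joins
isozymes.  The derivation rules implemented here are:

* a complex (AND node) is active iff *strictly more than 50%* of its distinct
  gene leaves are present; when active, missing subunits are pruned from the
  rule;
* an isozyme group (OR node) is active iff at least one alternative is active;
  inactive alternatives are pruned;
* a homolog of a reference gene is integrated by OR-ing a copy of every
  maximal AND-term containing the reference (with the reference substituted),
  or as a plain OR-sibling of a bare reference leaf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Tuple, Union

__all__ = [
    "Gene",
    "And",
    "Or",
    "GprTree",
    "GprParseError",
    "parse_gpr",
    "format_gpr",
    "evaluate_gpr",
    "integrate_homolog",
    "gene_leaves",
]


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: Tuple["GprTree", ...]


@dataclass(frozen=True)
class Or:
    children: Tuple["GprTree", ...]


GprTree = Union[Gene, And, Or]


class GprParseError(ValueError):
    """Raised on malformed GPR text; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


def _sort_key(node: GprTree) -> str:
    return format_gpr(node)


def normalize(node: GprTree) -> GprTree:
    """Flatten nested same-kind nodes, merge duplicate children, collapse
    single-child operators, and order children deterministically."""
    if isinstance(node, Gene):
        return node
    kind = type(node)
    flat: list[GprTree] = []
    for child in node.children:
        child = normalize(child)
        if isinstance(child, kind):
            flat.extend(child.children)
        else:
            flat.append(child)
    seen: dict[str, GprTree] = {}
    for child in flat:
        seen.setdefault(_sort_key(child), child)
    children = tuple(sorted(seen.values(), key=_sort_key))
    if len(children) == 1:
        return children[0]
    return kind(children)


def gene_leaves(node: GprTree) -> set[str]:
    if isinstance(node, Gene):
        return {node.name}
    out: set[str] = set()
    for child in node.children:
        out |= gene_leaves(child)
    return out


# ---------------------------------------------------------------------------
# parsing / formatting
# ---------------------------------------------------------------------------

_TOKEN_CHARS = set("()")


def _tokenize(text: str) -> Iterator[Tuple[str, str, int]]:
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in _TOKEN_CHARS:
            yield ("paren", c, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in _TOKEN_CHARS:
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            yield ("op", low, i)
        else:
            yield ("gene", word, i)
        i = j


class _Parser:
    """Precedence-climbing parser: ``and`` binds tighter than ``or``."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self):
        tok = self.peek()
        if tok is not None:
            self.pos += 1
        return tok

    def parse(self) -> GprTree:
        if not self.tokens:
            raise GprParseError("empty GPR expression", 0)
        node = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok[1]!r}", tok[2])
        return node

    def parse_or(self) -> GprTree:
        terms = [self.parse_and()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "op" and tok[1] == "or":
                self.next()
                terms.append(self.parse_and())
            else:
                break
        return terms[0] if len(terms) == 1 else Or(tuple(terms))

    def parse_and(self) -> GprTree:
        factors = [self.parse_atom()]
        while True:
            tok = self.peek()
            if tok is not None and tok[0] == "op" and tok[1] == "and":
                self.next()
                factors.append(self.parse_atom())
            else:
                break
        return factors[0] if len(factors) == 1 else And(tuple(factors))

    def parse_atom(self) -> GprTree:
        tok = self.next()
        if tok is None:
            raise GprParseError("dangling operator", len(self.text))
        kind, value, offset = tok
        if kind == "gene":
            return Gene(value)
        if kind == "paren" and value == "(":
            inner = self.parse_or()
            close = self.next()
            if close is None or close[1] != ")":
                raise GprParseError("unbalanced parentheses", offset)
            return inner
        raise GprParseError(f"unexpected token {value!r}", offset)


def parse_gpr(text: str) -> GprTree:
    """Parse a GPR string into a normalized tree.

    ``and`` binds tighter than ``or``; keywords are case-insensitive.
    """
    return normalize(_Parser(text).parse())


def format_gpr(node: Optional[GprTree]) -> str:
    """Serialize a tree back to the string dialect accepted by parse_gpr."""
    if node is None:
        return ""
    if isinstance(node, Gene):
        return node.name
    op = " and " if isinstance(node, And) else " or "
    parts = []
    for child in node.children:
        text = format_gpr(child)
        if isinstance(node, And) and isinstance(child, Or):
            text = f"({text})"
        elif isinstance(node, Or) and isinstance(child, And):
            text = f"({text})"
        parts.append(text)
    return op.join(parts)


# ---------------------------------------------------------------------------
# evaluation with the >50% complex rule
# ---------------------------------------------------------------------------

def _prune(node: GprTree, present: frozenset) -> Optional[GprTree]:
    """Return the pruned subtree if the node is active, else None."""
    if isinstance(node, Gene):
        return node if node.name in present else None
    if isinstance(node, And):
        leaves = gene_leaves(node)
        n_present = len(leaves & present)
        # strict majority of distinct subunit leaves
        if 2 * n_present <= len(leaves):
            return None
        kept = [_prune(c, present) for c in node.children]
        kept = [c for c in kept if c is not None]
        if not kept:
            return None
        return And(tuple(kept)) if len(kept) > 1 else kept[0]
    # Or
    kept = [_prune(c, present) for c in node.children]
    kept = [c for c in kept if c is not None]
    if not kept:
        return None
    return Or(tuple(kept)) if len(kept) > 1 else kept[0]


def evaluate_gpr(
    gpr: Optional[GprTree], present_genes
) -> Tuple[bool, Optional[GprTree]]:
    """Evaluate a GPR against a set of present ortholog groups.

    Returns ``(active, pruned)``.  A reaction with no GPR is always active
    (spontaneous / exchange reactions).  An AND complex is active iff
    strictly more than half of its distinct gene leaves are present, and its
    pruned form retains only the present subunits; OR isozymes drop inactive
    alternatives.  ``active=False`` implies ``pruned is None``.
    """
    if gpr is None:
        return True, None
    pruned = _prune(gpr, frozenset(present_genes))
    if pruned is None:
        return False, None
    return True, normalize(pruned)


# ---------------------------------------------------------------------------
# homolog integration
# ---------------------------------------------------------------------------

def _substitute(node: GprTree, reference: str, homolog: str) -> GprTree:
    if isinstance(node, Gene):
        return Gene(homolog) if node.name == reference else node
    kind = type(node)
    return kind(tuple(_substitute(c, reference, homolog) for c in node.children))


def _contains(node: GprTree, gene: str) -> bool:
    return gene in gene_leaves(node)


def integrate_homolog(
    gpr: GprTree, reference_gene: str, homolog_gene: str, logger=None
) -> GprTree:
    """OR-in a homolog alongside its reference gene.

    For every maximal AND-term containing the reference, a duplicate of the
    term with the reference replaced by the homolog is added as an OR
    alternative ("A and B" -> "(A and B) or (C and B)"); a bare reference
    leaf gains the homolog as an OR sibling ("A or B" -> "A or B or C").
    If the reference is absent the rule is returned unchanged with a warning.
    """
    if not _contains(gpr, reference_gene):
        if logger is not None:
            logger.warning(
                "reference gene %s not in GPR; homolog %s not integrated",
                reference_gene,
                homolog_gene,
            )
        return gpr

    def rewrite(node: GprTree) -> GprTree:
        if isinstance(node, Gene):
            if node.name == reference_gene:
                return Or((node, Gene(homolog_gene)))
            return node
        if isinstance(node, And):
            # maximal AND-term: duplicate wholesale with the reference swapped
            if _contains(node, reference_gene):
                return Or((node, _substitute(node, reference_gene, homolog_gene)))
            return node
        return Or(tuple(rewrite(c) for c in node.children))

    return normalize(rewrite(gpr))
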