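"""Model preprocessing: make every reaction irreversible and single-enzyme.

The pooled enzyme constraint charges each reaction's flux against one
(kcat, MW) pair, which requires (i) non-negative fluxes — a reversible
reaction's two directions may have different turnover numbers — and
(ii) exactly one enzyme per reaction — a reaction catalysed by several
isozymes must be split so each copy carries its own enzyme.

Reversible reactions become a forward copy and a ``<id>_reverse`` copy
with negated stoichiometry.  A GPR with *n* OR-alternatives yields *n*
copies ``<id>_num1`` … ``<id>_num<n>`` (BiGG-style, e.g. ALATA_D2_num1),
each annotated with one gene set (an isozyme or complex).  Reversibility
is split first, so a reversible two-isozyme reaction ends up as e.g.
``R_num1``, ``R_num2``, ``R_reverse_num1``, ``R_reverse_num2``.  Both
transformations are flux-equivalent: any objective optimum is preserved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .gem_io import MetabolicModel, Reaction

REVERSE_SUFFIX = "_reverse"
ISOZYME_SUFFIX = "_num"


class GPRSyntaxError(ValueError):
    """Malformed gene-protein-reaction rule; reports the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class SplitProvenance:
    """Maps one derived reaction back to its source reaction."""

    derived_id: str
    source_id: str
    direction: str = "none"  # {forward, reverse, none}
    isozyme_index: int | None = None


# --------------------------------------------------------------------------
# GPR parsing

_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(expr: str) -> list[tuple[str, str, int]]:
    """Yield (kind, text, position); kind in {lparen, rparen, and, or, gene}."""
    tokens = []
    pos = 0
    while pos < len(expr):
        m = _TOKEN_RE.match(expr, pos)
        if m is None:
            break
        text = m.group(1)
        tpos = m.start(1)
        low = text.lower()
        if text == "(":
            kind = "lparen"
        elif text == ")":
            kind = "rparen"
        elif low == "and":
            kind = "and"
        elif low == "or":
            kind = "or"
        else:
            kind = "gene"
        tokens.append((kind, text, tpos))
        pos = m.end()
    return tokens


class _GPRParser:
    """Recursive-descent parser producing disjunctive normal form.

    Grammar:  expr := term ("or" term)* ; term := factor ("and" factor)* ;
    factor := gene | "(" expr ")".  The DNF of a subexpression is a list
    of frozensets of gene ids.
    """

    def __init__(self, expr: str):
        self.expr = expr
        self.tokens = _tokenize(expr)
        self.i = 0

    def _peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self) -> tuple[str, str, int]:
        tok = self._peek()
        if tok is None:
            raise GPRSyntaxError("unexpected end of expression", len(self.expr))
        self.i += 1
        return tok

    def parse(self) -> list[frozenset[str]]:
        dnf = self._expr()
        tok = self._peek()
        if tok is not None:
            raise GPRSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return dnf

    def _expr(self) -> list[frozenset[str]]:
        alts = list(self._term())
        while (tok := self._peek()) is not None and tok[0] == "or":
            self._next()
            alts.extend(self._term())
        return alts

    def _term(self) -> list[frozenset[str]]:
        dnf = self._factor()
        while (tok := self._peek()) is not None and tok[0] == "and":
            self._next()
            rhs = self._factor()
            dnf = [a | b for a in dnf for b in rhs]
        return dnf

    def _factor(self) -> list[frozenset[str]]:
        tok = self._next()
        kind, text, pos = tok
        if kind == "gene":
            return [frozenset([text])]
        if kind == "lparen":
            inner = self._expr()
            closing = self._next()
            if closing[0] != "rparen":
                raise GPRSyntaxError(f"expected ')', got {closing[1]!r}", closing[2])
            return inner
        raise GPRSyntaxError(f"expected gene id or '(', got {text!r}", pos)


def parse_gpr(expr: str) -> list[frozenset[str]]:
    """Enzyme alternatives of a GPR rule, as DNF gene sets.

    Each returned set is one isozyme (singleton) or complex (AND-set).
    Exact duplicates are removed (first occurrence kept); an alternative
    that is a superset of another is retained, because a complex may
    legitimately contain all genes of a smaller alternative.  The empty
    expression yields an empty list (spontaneous reaction).
    """
    if not expr or not expr.strip():
        return []
    dnf = _GPRParser(expr).parse()
    seen: set[frozenset[str]] = set()
    out: list[frozenset[str]] = []
    for alt in dnf:
        if alt not in seen:
            seen.add(alt)
            out.append(alt)
    return out


# --------------------------------------------------------------------------
# splitting

def split_reversible(model: MetabolicModel) -> tuple[MetabolicModel, list[SplitProvenance]]:
    """Split every reversible reaction into forward and reverse irreversible copies.

    A reaction with lb < 0 < ub becomes ``id`` (bounds [0, ub], original
    stoichiometry) and ``id_reverse`` (bounds [0, -lb], negated
    stoichiometry).  A purely backward reaction (ub ≤ 0) is flipped in
    place.  Afterwards every bound satisfies 0 ≤ lb ≤ ub.
    """
    reactions: list[Reaction] = []
    provenance: list[SplitProvenance] = []
    for r in model.reactions:
        if r.lower_bound < 0 < r.upper_bound:
            fwd = r.copy()
            fwd.lower_bound = 0.0
            rev = r.copy()
            rev.id = r.id + REVERSE_SUFFIX
            rev.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
            rev.lower_bound = 0.0
            rev.upper_bound = -r.lower_bound
            reactions.extend([fwd, rev])
            provenance.append(SplitProvenance(fwd.id, r.id, "forward"))
            provenance.append(SplitProvenance(rev.id, r.id, "reverse"))
        elif r.upper_bound <= 0:
            flipped = r.copy()
            flipped.stoichiometry = {m: -c for m, c in r.stoichiometry.items()}
            flipped.lower_bound = -r.upper_bound
            flipped.upper_bound = -r.lower_bound
            reactions.append(flipped)
            provenance.append(SplitProvenance(flipped.id, r.id, "reverse"))
        else:
            reactions.append(r.copy())
    return (
        MetabolicModel(
            metabolites=list(model.metabolites),
            reactions=reactions,
            genes=list(model.genes),
            objective_reaction=model.objective_reaction,
            id=model.id,
        ),
        provenance,
    )


def split_isozymes(model: MetabolicModel) -> tuple[MetabolicModel, list[SplitProvenance]]:
    """Replace each multi-isozyme reaction by one copy per enzyme alternative.

    A reaction whose GPR has n > 1 alternatives becomes ``id_num1`` …
    ``id_num<n>`` with identical stoichiometry and bounds, each carrying
    a single gene set in ``enzyme_genes``.  Reactions with 0 or 1
    alternatives are kept (annotated but not renamed).
    """
    reactions: list[Reaction] = []
    provenance: list[SplitProvenance] = []
    for r in model.reactions:
        alternatives = parse_gpr(r.gpr)
        if len(alternatives) <= 1:
            kept = r.copy()
            kept.enzyme_genes = alternatives[0] if alternatives else frozenset()
            reactions.append(kept)
            continue
        for k, genes in enumerate(alternatives, start=1):
            copy = r.copy()
            copy.id = f"{r.id}{ISOZYME_SUFFIX}{k}"
            copy.gpr = " and ".join(sorted(genes))
            copy.enzyme_genes = genes
            reactions.append(copy)
            provenance.append(SplitProvenance(copy.id, r.id, "none", isozyme_index=k))
    return (
        MetabolicModel(
            metabolites=list(model.metabolites),
            reactions=reactions,
            genes=list(model.genes),
            objective_reaction=model.objective_reaction,
            id=model.id,
        ),
        provenance,
    )


def preprocess(model: MetabolicModel) -> tuple[MetabolicModel, list[SplitProvenance]]:
    """Full preprocessing: reversibility split, then isozyme split.

    Provenance entries map every derived reaction to its ultimate source
    reaction in the input model (direction and isozyme index combined).
    """
    split_rev, prov_rev = split_reversible(model)
    final, prov_iso = split_isozymes(split_rev)
    rev_source = {p.derived_id: p for p in prov_rev}
    provenance: list[SplitProvenance] = []
    consumed: set[str] = set()
    for p in prov_iso:
        base = rev_source.get(p.source_id)
        if base is not None:
            consumed.add(p.source_id)
            provenance.append(
                SplitProvenance(p.derived_id, base.source_id, base.direction, p.isozyme_index)
            )
        else:
            provenance.append(p)
    provenance.extend(p for p in prov_rev if p.derived_id not in consumed)
    return final, provenance


def source_id(derived_id: str) -> str:
    """Strip split suffixes to recover the original reaction id."""
    rid = derived_id
    if ISOZYME_SUFFIX in rid:
        base, _, tail = rid.rpartition(ISOZYME_SUFFIX)
        if tail.isdigit():
            rid = base
    if rid.endswith(REVERSE_SUFFIX):
        rid = rid[: -len(REVERSE_SUFFIX)]
    return rid


def provenance_to_tsv(provenance: Iterable[SplitProvenance], path) -> None:
    rows = [
        {"derived_id": p.derived_id, "source_id": p.source_id,
         "direction": p.direction, "isozyme_index": p.isozyme_index}
        for p in provenance
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
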