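"""Core metabolic-model data structures and gene-reaction-rule logic.

A :class:`MetabolicModel` is a stoichiometric network: metabolites, reactions
with flux bounds, and boolean gene-protein-reaction (GPR) rules linking each
reaction to the genes whose products catalyse it.  The steady-state constraint
``S @ v = 0`` together with the box bounds ``lb <= v <= ub`` defines the flux
polytope that every downstream operation (FBA, FVA, uniform sampling) works on.

GPR rules use three-valued (Kleene) logic so that genes that were never
measured propagate as ``unknown`` rather than silently counting as present or
absent: an AND node is inactive as soon as one subunit is absent, an OR node
is active as soon as one isozyme is present.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelValidationError",
    "GPRSyntaxError",
    "parse_gpr",
    "evaluate_gpr",
    "gpr_genes",
    "stoichiometric_matrix",
    "ACTIVE",
    "INACTIVE",
    "UNKNOWN",
]

DEFAULT_BOUND = 1000.0

ACTIVE = "active"
INACTIVE = "inactive"
UNKNOWN = "unknown"


class ModelValidationError(ValueError):
    """A model violates a structural invariant (duplicate ids, bad refs...)."""


class GPRSyntaxError(ValueError):
    """A gene-reaction rule string could not be parsed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str = "c"
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(
                f"metabolite {self.id!r}: compartment must be non-empty"
            )


@dataclass
class Reaction:
    """One reaction: signed stoichiometry, flux bounds and an optional GPR.

    ``stoich`` maps metabolite id -> coefficient (negative = consumed).
    An empty ``gpr`` string means the reaction has no gene dependency
    (spontaneous or transport) and is always considered active.
    """

    id: str
    stoich: Dict[str, float] = field(default_factory=dict)
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    gpr: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if self.lb > self.ub:
            raise ModelValidationError(
                f"reaction {self.id!r}: lb ({self.lb}) > ub ({self.ub})"
            )

    @property
    def reversible(self) -> bool:
        return self.lb < 0 < self.ub

    @property
    def is_boundary(self) -> bool:
        """True for exchange/demand reactions touching a single metabolite."""
        return len(self.stoich) == 1


@dataclass
class MetabolicModel:
    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    objective: Optional[str] = None
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    @property
    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction with id {rid!r}")

    def genes(self) -> List[str]:
        out: set[str] = set()
        for r in self.reactions:
            out.update(gpr_genes(r.gpr))
        return sorted(out)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(mids) != len(set(mids)):
            dup = sorted({i for i in mids if mids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            dup = sorted({i for i in rids if rids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        known = set(mids)
        for r in self.reactions:
            missing = set(r.stoich) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references undeclared metabolites: "
                    f"{sorted(missing)}"
                )
        if self.objective is not None and self.objective not in set(rids):
            raise ModelValidationError(
                f"objective reaction {self.objective!r} not in model"
            )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[
                Reaction(r.id, dict(r.stoich), r.lb, r.ub, r.gpr, r.subsystem)
                for r in self.reactions
            ],
            objective=self.objective,
            provenance=list(self.provenance),
        )

    def subset(self, keep_reactions: Iterable[str]) -> "MetabolicModel":
        """Sub-model with the given reactions; drops orphaned metabolites."""
        keep = set(keep_reactions)
        unknown = keep - set(self.reaction_ids)
        if unknown:
            raise KeyError(f"unknown reaction ids: {sorted(unknown)}")
        reactions = [
            Reaction(r.id, dict(r.stoich), r.lb, r.ub, r.gpr, r.subsystem)
            for r in self.reactions
            if r.id in keep
        ]
        used = set()
        for r in reactions:
            used.update(r.stoich)
        metabolites = [m for m in self.metabolites if m.id in used]
        obj = self.objective if self.objective in keep else None
        return MetabolicModel(
            metabolites=metabolites,
            reactions=reactions,
            objective=obj,
            provenance=list(self.provenance),
        )


def stoichiometric_matrix(model: MetabolicModel) -> np.ndarray:
    """Assemble S (metabolites x reactions); S[i, j] is the coefficient of
    metabolite i in reaction j, zero where the metabolite does not take part."""
    index = {m.id: i for i, m in enumerate(model.metabolites)}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoich.items():
            S[index[mid], j] = coef
    return S


# ---------------------------------------------------------------------------
# GPR parsing and three-valued evaluation
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

# parsed form: ("gene", id) | ("and", [children]) | ("or", [children])
GPRNode = Tuple


def _tokenize(expr: str) -> List[str]:
    return _TOKEN_RE.findall(expr)


def parse_gpr(expr: str) -> Optional[GPRNode]:
    """Parse a GPR string into an AND/OR tree; ``None`` for the empty rule.

    Grammar (case-insensitive keywords, standard precedence AND > OR)::

        expr   := term ( OR term )*
        term   := factor ( AND factor )*
        factor := '(' expr ')' | gene-id
    """
    tokens = _tokenize(expr)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> GPRNode:
        children = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            children.append(parse_term())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_term() -> GPRNode:
        children = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            children.append(parse_factor())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_factor() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR expression: {expr!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR: {expr!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"unexpected token {tok!r} in GPR: {expr!r}")
        return ("gene", take())

    node = parse_expr()
    if pos != len(tokens):
        raise GPRSyntaxError(
            f"trailing tokens {tokens[pos:]} in GPR expression: {expr!r}"
        )
    return node


def gpr_genes(expr: str) -> List[str]:
    """All gene ids mentioned in a GPR string (sorted, unique)."""
    node = parse_gpr(expr)
    out: set[str] = set()

    def walk(n) -> None:
        if n is None:
            return
        kind = n[0]
        if kind == "gene":
            out.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return sorted(out)


def _eval_node(node, calls: Mapping[str, str]) -> str:
    kind = node[0]
    if kind == "gene":
        call = calls.get(node[1], "unmeasured")
        if call == "present":
            return ACTIVE
        if call == "absent":
            return INACTIVE
        return UNKNOWN
    states = [_eval_node(c, calls) for c in node[1]]
    if kind == "and":
        if INACTIVE in states:
            return INACTIVE
        if UNKNOWN in states:
            return UNKNOWN
        return ACTIVE
    # or
    if ACTIVE in states:
        return ACTIVE
    if UNKNOWN in states:
        return UNKNOWN
    return INACTIVE


def evaluate_gpr(expr: str, calls: Mapping[str, str]) -> str:
    """Evaluate a GPR against per-gene presence calls.

    ``calls`` maps gene id -> {"present", "absent", "unmeasured"}; genes not
    in the mapping count as unmeasured.  Returns ``"active"``, ``"inactive"``
    or ``"unknown"``; the empty rule is always active.
    """
    node = parse_gpr(expr)
    if node is None:
        return ACTIVE
    return _eval_node(node, calls)
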