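"""In-memory representation of a compartmentalized metabolic model.

Provides metabolites, reactions with flux bounds and gene-protein-reaction
(GPR) boolean rules, the assembled model object, stoichiometric-matrix
construction and elemental bookkeeping helpers.

Conventions
-----------
* Fluxes are in mmol gDW^-1 h^-1; the biomass reaction flux is in h^-1.
* Exchange reactions are written ``met[e] <=> (nothing)``: negative flux is
  uptake, positive flux is secretion.
* Default bounds: irreversible reactions [0, 1000], reversible
  [-1000, 1000]; 1000 acts as the conventional "unbounded" sentinel.
"""

from __future__ import annotations

import copy as _copy
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

UNBOUNDED = 1000.0

#: default compartment registry: suffix -> descriptive name
DEFAULT_COMPARTMENTS = {
    "e": "extracellular",
    "c": "cytosol",
    "m": "mitochondrion",
    "x": "peroxisome",
}


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


class GprParseError(ValueError):
    """Raised when a GPR expression cannot be parsed; carries the position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

_GPR_TOKEN = re.compile(r"\s*(\(|\)|,|[^\s(),]+)")


def _tokenize_gpr(expression: str):
    tokens = []
    pos = 0
    while pos < len(expression):
        m = _GPR_TOKEN.match(expression, pos)
        if m is None:  # only trailing whitespace remains
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


class _GprParser:
    """Recursive-descent parser; AND binds tighter than OR, ',' means OR."""

    def __init__(self, expression: str):
        self.expression = expression
        self.tokens = _tokenize_gpr(expression)
        self.index = 0

    def peek(self):
        if self.index < len(self.tokens):
            return self.tokens[self.index]
        return (None, len(self.expression))

    def advance(self):
        tok = self.peek()
        self.index += 1
        return tok

    def parse(self):
        if not self.tokens:
            return None
        node = self.parse_or()
        tok, pos = self.peek()
        if tok is not None:
            raise GprParseError(f"unexpected token {tok!r}", pos)
        return node

    def parse_or(self):
        terms = [self.parse_and()]
        while True:
            tok, _ = self.peek()
            if tok is not None and (tok.lower() == "or" or tok == ","):
                self.advance()
                terms.append(self.parse_and())
            else:
                break
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and(self):
        terms = [self.parse_atom()]
        while True:
            tok, _ = self.peek()
            if tok is not None and tok.lower() == "and":
                self.advance()
                terms.append(self.parse_atom())
            else:
                break
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom(self):
        tok, pos = self.advance()
        if tok is None:
            raise GprParseError("unexpected end of expression", pos)
        if tok == "(":
            node = self.parse_or()
            closing, cpos = self.advance()
            if closing != ")":
                raise GprParseError("expected ')'", cpos)
            return node
        if tok in {")", ","} or tok.lower() in {"and", "or"}:
            raise GprParseError(f"unexpected token {tok!r}", pos)
        return ("gene", tok)


class GprRule:
    """Boolean gene association; empty expression means "no gene required".

    Grammar: infix boolean over gene identifiers with ``and``/``or``
    (case-insensitive) and parentheses; a comma is accepted as ``or`` so
    isozyme lists such as ``"g1, g2, g3"`` parse naturally.
    """

    __slots__ = ("expression", "_tree")

    def __init__(self, expression: str = ""):
        self.expression = expression.strip()
        self._tree = _GprParser(self.expression).parse()

    @property
    def tree(self):
        return self._tree

    @property
    def is_empty(self) -> bool:
        return self._tree is None

    def genes(self) -> frozenset:
        """Set of gene ids appearing as leaves."""
        out = set()

        def walk(node):
            if node is None:
                return
            kind = node[0]
            if kind == "gene":
                out.add(node[1])
            else:
                for child in node[1]:
                    walk(child)

        walk(self._tree)
        return frozenset(out)

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """Truth value with the deleted genes set to False, others True."""
        deleted = set(deleted_genes)

        def walk(node) -> bool:
            kind = node[0]
            if kind == "gene":
                return node[1] not in deleted
            if kind == "and":
                return all(walk(child) for child in node[1])
            return any(walk(child) for child in node[1])

        if self._tree is None:
            return True
        return walk(self._tree)

    def to_string(self) -> str:
        """Canonical serialization with explicit parentheses on OR-in-AND."""

        def render(node, parent: str) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            joiner = f" {kind} "
            text = joiner.join(render(child, kind) for child in node[1])
            if kind == "or" and parent == "and":
                return f"({text})"
            return text

        if self._tree is None:
            return ""
        return render(self._tree, "")

    def __repr__(self):
        return f"GprRule({self.to_string()!r})"

    def __eq__(self, other):
        return isinstance(other, GprRule) and self._tree == other._tree

    def __hash__(self):
        return hash(self.to_string())


def evaluate_gpr(rule: GprRule, deleted_genes: Iterable[str] = ()) -> bool:
    """Is the reaction guarded by `rule` still active after the deletion?"""
    if isinstance(rule, str):
        rule = GprRule(rule)
    return rule.evaluate(deleted_genes)


# ---------------------------------------------------------------------------
# Metabolites, reactions, model
# ---------------------------------------------------------------------------


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None
    charge: Optional[int] = None

    def copy(self) -> "Metabolite":
        return _copy.copy(self)


REACTION_TYPES = ("biochemical", "transport", "exchange")


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: dict = field(default_factory=dict)
    lower_bound: float = 0.0
    upper_bound: float = UNBOUNDED
    rtype: str = "biochemical"
    subsystem: str = ""
    gpr: GprRule = field(default_factory=GprRule)

    def __post_init__(self):
        if isinstance(self.gpr, str):
            self.gpr = GprRule(self.gpr)

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def bounds(self):
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, value):
        self.lower_bound, self.upper_bound = value

    def copy(self) -> "Reaction":
        new = _copy.copy(self)
        new.stoichiometry = dict(self.stoichiometry)
        return new


class MetabolicModel:
    """A compartmentalized stoichiometric model with GPR associations.

    Metabolite/reaction ordering is the insertion order and is stable; the
    stoichiometric matrix rows/columns follow it.
    """

    def __init__(
        self,
        id: str = "model",
        name: str = "",
        compartments: Optional[Mapping[str, str]] = None,
    ):
        self.id = id
        self.name = name
        self.compartments = dict(
            compartments if compartments is not None else DEFAULT_COMPARTMENTS
        )
        self.metabolites: list[Metabolite] = []
        self.reactions: list[Reaction] = []
        self.genes: list[str] = []
        self.objective_id: Optional[str] = None
        self._met_index: dict[str, int] = {}
        self._rxn_index: dict[str, int] = {}

    # -- construction ------------------------------------------------------

    def add_metabolite(self, metabolite: Metabolite) -> Metabolite:
        if metabolite.id in self._met_index:
            raise ModelStructureError(f"duplicate metabolite id {metabolite.id!r}")
        if metabolite.compartment not in self.compartments:
            raise ModelStructureError(
                f"metabolite {metabolite.id!r} uses unregistered compartment "
                f"{metabolite.compartment!r}"
            )
        self._met_index[metabolite.id] = len(self.metabolites)
        self.metabolites.append(metabolite)
        return metabolite

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if reaction.id in self._rxn_index:
            raise ModelStructureError(f"duplicate reaction id {reaction.id!r}")
        for met_id in reaction.stoichiometry:
            if met_id not in self._met_index:
                raise ModelStructureError(
                    f"reaction {reaction.id!r} references unknown metabolite "
                    f"{met_id!r}"
                )
        self._rxn_index[reaction.id] = len(self.reactions)
        self.reactions.append(reaction)
        for gene in reaction.gpr.genes():
            if gene not in self.genes:
                self.genes.append(gene)
        return reaction

    def remove_reaction(self, reaction_id: str) -> Reaction:
        idx = self.reaction_index(reaction_id)
        removed = self.reactions.pop(idx)
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self.genes = sorted(
            set().union(*(r.gpr.genes() for r in self.reactions))
            if self.reactions
            else set()
        )
        if self.objective_id == reaction_id:
            self.objective_id = None
        return removed

    # -- lookups -----------------------------------------------------------

    @property
    def n_met(self) -> int:
        return len(self.metabolites)

    @property
    def n_rxn(self) -> int:
        return len(self.reactions)

    def metabolite_index(self, met_id: str) -> int:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"unknown metabolite {met_id!r}") from None

    def reaction_index(self, rxn_id: str) -> int:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"unknown reaction {rxn_id!r}") from None

    def metabolite(self, met_id: str) -> Metabolite:
        return self.metabolites[self.metabolite_index(met_id)]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self.reaction_index(rxn_id)]

    def has_metabolite(self, met_id: str) -> bool:
        return met_id in self._met_index

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.rtype == "exchange"]

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(self.id, self.name, self.compartments)
        for met in self.metabolites:
            new.add_metabolite(met.copy())
        for rxn in self.reactions:
            new.add_reaction(rxn.copy())
        new.genes = list(self.genes)
        new.objective_id = self.objective_id
        return new

    # -- validation --------------------------------------------------------

    def reaction_compartments(self, reaction: Reaction) -> set:
        return {
            self.metabolite(met_id).compartment for met_id in reaction.stoichiometry
        }

    def validate(self, check_charge: bool = False) -> None:
        """Raise :class:`ModelStructureError` on any structural violation.

        Charge imbalance is never a hard error; with ``check_charge`` it is
        emitted as a warning.
        """
        for rxn in self.reactions:
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelStructureError(
                    f"reaction {rxn.id!r}: lower bound exceeds upper bound"
                )
            if rxn.rtype not in REACTION_TYPES:
                raise ModelStructureError(
                    f"reaction {rxn.id!r}: unknown rtype {rxn.rtype!r}"
                )
            for met_id in rxn.stoichiometry:
                if met_id not in self._met_index:
                    raise ModelStructureError(
                        f"reaction {rxn.id!r} references unknown metabolite "
                        f"{met_id!r}"
                    )
            comps = self.reaction_compartments(rxn)
            if rxn.rtype == "exchange":
                if len(rxn.stoichiometry) != 1:
                    raise ModelStructureError(
                        f"exchange reaction {rxn.id!r} must have exactly one "
                        "metabolite"
                    )
                comp = next(iter(comps))
                if self.compartments.get(comp) != "extracellular":
                    raise ModelStructureError(
                        f"exchange reaction {rxn.id!r} metabolite is not "
                        "extracellular"
                    )
            elif rxn.rtype == "transport":
                if len(comps) < 2:
                    raise ModelStructureError(
                        f"transport reaction {rxn.id!r} spans fewer than two "
                        "compartments"
                    )
            else:
                if len(comps) > 1:
                    raise ModelStructureError(
                        f"biochemical reaction {rxn.id!r} spans multiple "
                        f"compartments {sorted(comps)}"
                    )
        gpr_genes = set()
        for rxn in self.reactions:
            gpr_genes |= rxn.gpr.genes()
        if gpr_genes != set(self.genes):
            raise ModelStructureError(
                "gene list does not equal the union of GPR leaves "
                f"(extra: {sorted(set(self.genes) - gpr_genes)}, "
                f"missing: {sorted(gpr_genes - set(self.genes))})"
            )
        if self.objective_id is not None and self.objective_id not in self._rxn_index:
            raise ModelStructureError(
                f"objective reaction {self.objective_id!r} does not exist"
            )
        if check_charge:
            for rxn in self.reactions:
                if rxn.rtype != "biochemical":
                    continue
                imbalance = charge_imbalance(self, rxn)
                if imbalance is not None and abs(imbalance) > 1e-9:
                    warnings.warn(
                        f"reaction {rxn.id!r} charge imbalance {imbalance:+g}",
                        stacklevel=2,
                    )

    def __repr__(self):
        return (
            f"<MetabolicModel {self.id}: {self.n_met} metabolites, "
            f"{self.n_rxn} reactions, {len(self.genes)} genes>"
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def build_stoichiometric_matrix(
    model: MetabolicModel, sparse_format: bool = False
) -> np.ndarray:
    """Stoichiometric matrix S of shape (n_met, n_rxn).

    Entry (i, j) is the signed coefficient of metabolite i in reaction j
    (negative = consumed). Row order follows ``model.metabolites``, column
    order ``model.reactions``.
    """
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            try:
                i = model.metabolite_index(met_id)
            except KeyError:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite "
                    f"{met_id!r}"
                ) from None
            rows.append(i)
            cols.append(j)
            data.append(float(coef))
    matrix = sparse.coo_matrix(
        (data, (rows, cols)), shape=(model.n_met, model.n_rxn)
    ).tocsr()
    if sparse_format:
        return matrix
    return matrix.toarray()


def reactions_involving(
    model: MetabolicModel,
    metabolite_id: str,
    compartment: Optional[str] = None,
) -> set:
    """Ids of reactions whose stoichiometry references the metabolite.

    With ``compartment``, only reactions that touch the metabolite in that
    compartment are returned (the metabolite id itself already encodes its
    compartment, so this simply filters on it).
    """
    met = model.metabolite(metabolite_id)
    if compartment is not None and met.compartment != compartment:
        return set()
    return {r.id for r in model.reactions if metabolite_id in r.stoichiometry}


# ---------------------------------------------------------------------------
# Elemental bookkeeping
# ---------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict:
    """Parse ``"C6H12O6"``-style formulas into an element->count map."""
    if not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed formula {formula!r}")
    counts: dict[str, float] = {}
    for element, count in _FORMULA_TOKEN.findall(formula):
        counts[element] = counts.get(element, 0) + (int(count) if count else 1)
    return counts


def elemental_imbalance(model: MetabolicModel, reaction: Reaction):
    """Net element counts produced minus consumed, or None.

    Returns None when any participating metabolite lacks a formula (the
    reaction then cannot be audited). A fully balanced reaction returns an
    empty dict.
    """
    net: dict[str, float] = {}
    for met_id, coef in reaction.stoichiometry.items():
        met = model.metabolite(met_id)
        if met.formula is None:
            return None
        for element, count in parse_formula(met.formula).items():
            net[element] = net.get(element, 0.0) + coef * count
    return {el: val for el, val in net.items() if abs(val) > 1e-9}


def charge_imbalance(model: MetabolicModel, reaction: Reaction):
    """Net charge produced minus consumed, or None if any charge missing."""
    net = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        met = model.metabolite(met_id)
        if met.charge is None:
            return None
        net += coef * met.charge
    return net
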