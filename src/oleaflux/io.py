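"""Model and result serialization.

Formats
-------
* SBML Level 3 + FBC version 2 (primary interchange), written and read with
  python-libsbml. Flux bounds travel as FBC bound parameters, GPRs as FBC
  gene-product associations, the objective as the active FBC objective.
* A plain-text TSV bundle (``reactions.tsv``, ``metabolites.tsv``,
  ``genes.tsv``) whose reaction equations round-trip exactly.
* Result tables (flux distributions, FVA ranges, reports) as TSV with
  floats at 6 significant digits.

Equation dialect: ``2 A[c] + 3 B[c] -> C[m]``; accepted arrows are ``->``
and ``=>`` (irreversible) and ``<=>`` / ``<->`` (reversible); an empty
right- or left-hand side marks an exchange reaction. Compartments are
encoded as ``[e] [c] [m] [x]`` id suffixes.
"""

from __future__ import annotations

import csv
import logging
import re
from pathlib import Path
from typing import Optional

from .core import (
    DEFAULT_COMPARTMENTS,
    UNBOUNDED,
    GprRule,
    MetabolicModel,
    Metabolite,
    ModelStructureError,
    Reaction,
)

logger = logging.getLogger(__name__)

_ARROWS = ["<=>", "<->", "=>", "->"]


class EquationParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Reaction equation strings
# ---------------------------------------------------------------------------


def parse_equation(equation: str) -> tuple[dict, bool]:
    """Parse an equation string into (stoichiometry map, reversible flag)."""
    arrow = None
    for candidate in _ARROWS:
        if candidate in equation:
            arrow = candidate
            break
    if arrow is None:
        raise EquationParseError(f"no reaction arrow in {equation!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(text: str, sign: float):
        text = text.strip()
        if not text:
            return
        for term in text.split(" + "):
            term = term.strip()
            if not term:
                raise EquationParseError(f"empty term in {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coef, met_id = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coef = float(parts[0])
                except ValueError:
                    raise EquationParseError(
                        f"bad coefficient {parts[0]!r} in {equation!r}"
                    ) from None
                met_id = parts[1]
            else:
                raise EquationParseError(f"malformed term {term!r} in {equation!r}")
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    if not stoich:
        raise EquationParseError(f"equation {equation!r} has no metabolites")
    return stoich, reversible


def _format_coefficient(value: float) -> str:
    """Shortest exact decimal for a float (never rounded)."""
    text = repr(float(abs(value)))
    return text[:-2] if text.endswith(".0") else text


def format_equation(reaction: Reaction) -> str:
    """Serialize stoichiometry back to the equation dialect (sorted sides)."""
    left, right = [], []
    for met_id in sorted(reaction.stoichiometry):
        coef = reaction.stoichiometry[met_id]
        target = left if coef < 0 else right
        mag = abs(coef)
        term = met_id if mag == 1 else f"{_format_coefficient(mag)} {met_id}"
        target.append(term)
    arrow = "<=>" if reaction.reversible else "->"
    return f"{' + '.join(left)} {arrow} {' + '.join(right)}".strip()


# ---------------------------------------------------------------------------
# Tabular bundle
# ---------------------------------------------------------------------------

_REACTION_COLUMNS = [
    "id",
    "name",
    "equation",
    "lower_bound",
    "upper_bound",
    "subsystem",
    "rtype",
    "gpr",
]
_METABOLITE_COLUMNS = ["id", "name", "compartment", "formula", "charge"]


def write_tabular_model(model: MetabolicModel, bundle_dir) -> None:
    """Write reactions.tsv / metabolites.tsv / genes.tsv into a directory."""
    bundle = Path(bundle_dir)
    bundle.mkdir(parents=True, exist_ok=True)
    with open(bundle / "metabolites.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_METABOLITE_COLUMNS)
        for met in model.metabolites:
            writer.writerow(
                [
                    met.id,
                    met.name,
                    met.compartment,
                    met.formula or "",
                    "" if met.charge is None else met.charge,
                ]
            )
    with open(bundle / "reactions.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_REACTION_COLUMNS + ["objective"])
        for rxn in model.reactions:
            writer.writerow(
                [
                    rxn.id,
                    rxn.name,
                    format_equation(rxn),
                    _format_coefficient(rxn.lower_bound)
                    if rxn.lower_bound >= 0
                    else "-" + _format_coefficient(rxn.lower_bound),
                    _format_coefficient(rxn.upper_bound)
                    if rxn.upper_bound >= 0
                    else "-" + _format_coefficient(rxn.upper_bound),
                    rxn.subsystem,
                    rxn.rtype,
                    rxn.gpr.to_string(),
                    "1" if rxn.id == model.objective_id else "",
                ]
            )
    with open(bundle / "genes.tsv", "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["id", "name"])
        for gene in model.genes:
            writer.writerow([gene, gene])


def read_tabular_model(bundle_dir) -> MetabolicModel:
    """Read a TSV bundle written by :func:`write_tabular_model`."""
    bundle = Path(bundle_dir)
    model = MetabolicModel(id=bundle.name or "model")
    with open(bundle / "metabolites.tsv", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                model.add_metabolite(
                    Metabolite(
                        id=row["id"],
                        name=row.get("name", ""),
                        compartment=row["compartment"],
                        formula=row.get("formula") or None,
                        charge=int(row["charge"]) if row.get("charge") else None,
                    )
                )
            except (KeyError, ValueError, ModelStructureError) as exc:
                raise ModelStructureError(
                    f"metabolites.tsv line {lineno}: {exc}"
                ) from exc
    with open(bundle / "reactions.tsv", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                stoich, reversible = parse_equation(row["equation"])
                lo = float(row["lower_bound"]) if row.get("lower_bound") else (
                    -UNBOUNDED if reversible else 0.0
                )
                hi = float(row["upper_bound"]) if row.get("upper_bound") else UNBOUNDED
                rxn = Reaction(
                    id=row["id"],
                    name=row.get("name", ""),
                    stoichiometry=stoich,
                    lower_bound=lo,
                    upper_bound=hi,
                    subsystem=row.get("subsystem", ""),
                    rtype=row.get("rtype") or _infer_rtype(model, stoich),
                    gpr=GprRule(row.get("gpr", "")),
                )
                model.add_reaction(rxn)
                if row.get("objective"):
                    model.objective_id = rxn.id
            except (EquationParseError, ValueError, ModelStructureError) as exc:
                raise ModelStructureError(
                    f"reactions.tsv line {lineno}: {exc}"
                ) from exc
    genes_path = bundle / "genes.tsv"
    if genes_path.exists():
        with open(genes_path, newline="") as handle:
            reader = csv.DictReader(handle, delimiter="\t")
            listed = [row["id"] for row in reader]
        if set(listed) != set(model.genes):
            logger.warning(
                "genes.tsv disagrees with GPR leaves; keeping GPR-derived list"
            )
    return model


def _infer_rtype(model: MetabolicModel, stoich: dict) -> str:
    comps = {model.metabolite(met_id).compartment for met_id in stoich}
    if len(stoich) == 1 and comps == {"e"}:
        return "exchange"
    if len(comps) > 1:
        return "transport"
    return "biochemical"


# ---------------------------------------------------------------------------
# SBML (Level 3 + FBC v2)
# ---------------------------------------------------------------------------

_SBML_ID_FIX = re.compile(r"[^A-Za-z0-9_]")
_TAGGED_ID = re.compile(r"^([A-Za-z0-9_]+)\[([a-z0-9]+)\]$")


def _to_sid(raw: str) -> str:
    """Bijective SBML id encoding for ids of the form ``base[tag]``.

    ``glc[e]`` becomes ``glc__e__``; ids already made of SBML-safe
    characters pass through unchanged. Other characters are sanitized to
    ``_`` (such ids will not round-trip bit-exact and are discouraged).
    """
    m = _TAGGED_ID.match(raw)
    if m:
        return f"{m.group(1)}__{m.group(2)}__"
    sid = _SBML_ID_FIX.sub("_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    return sid


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3V1 with the FBC v2 package."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    document = libsbml.SBMLDocument(ns)
    document.setPackageRequired("fbc", False)
    sbml_model = document.createModel()
    sbml_model.setId(_to_sid(model.id))
    sbml_model.setName(model.name or model.id)
    fbc = sbml_model.getPlugin("fbc")
    fbc.setStrict(True)

    for suffix in sorted(model.compartments):
        comp = sbml_model.createCompartment()
        comp.setId(_to_sid(suffix))
        comp.setName(model.compartments[suffix])
        comp.setConstant(True)

    id_map = {}
    for met in model.metabolites:
        species = sbml_model.createSpecies()
        sid = "M_" + _to_sid(met.id)
        id_map[met.id] = sid
        species.setId(sid)
        species.setName(met.name or met.id)
        species.setCompartment(_to_sid(met.compartment))
        species.setHasOnlySubstanceUnits(False)
        species.setBoundaryCondition(False)
        species.setConstant(False)
        splug = species.getPlugin("fbc")
        if met.formula is not None:
            splug.setChemicalFormula(met.formula)
        if met.charge is not None:
            splug.setCharge(int(met.charge))
        # keep the native id (with its compartment tag) recoverable
        species.setMetaId("meta_" + sid)

    def bound_parameter(value: float, tag: str) -> str:
        pid = f"bnd_{tag}"
        param = sbml_model.createParameter()
        param.setId(pid)
        param.setValue(float(value))
        param.setConstant(True)
        return pid

    for rxn in model.reactions:
        sbml_rxn = sbml_model.createReaction()
        rid = "R_" + _to_sid(rxn.id)
        sbml_rxn.setId(rid)
        sbml_rxn.setName(rxn.name or rxn.id)
        sbml_rxn.setReversible(rxn.reversible)
        sbml_rxn.setFast(False)
        if rxn.subsystem or rxn.rtype:
            note = (
                "<body xmlns='http://www.w3.org/1999/xhtml'>"
                f"<p>SUBSYSTEM: {rxn.subsystem}</p><p>RTYPE: {rxn.rtype}</p>"
                "</body>"
            )
            sbml_rxn.setNotes(note)
        for met_id in sorted(rxn.stoichiometry):
            coef = rxn.stoichiometry[met_id]
            ref = (
                sbml_rxn.createReactant() if coef < 0 else sbml_rxn.createProduct()
            )
            ref.setSpecies(id_map[met_id])
            ref.setStoichiometry(abs(float(coef)))
            ref.setConstant(True)
        rplug = sbml_rxn.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_parameter(rxn.lower_bound, f"lo_{_to_sid(rxn.id)}"))
        rplug.setUpperFluxBound(bound_parameter(rxn.upper_bound, f"hi_{_to_sid(rxn.id)}"))
        if not rxn.gpr.is_empty:
            assoc = rplug.createGeneProductAssociation()
            # tokens are treated as gene-product labels; missing gene
            # products are created on the fly by libsbml
            assoc.setAssociation(_gpr_to_fbc_infix(rxn.gpr))

    if model.objective_id is not None:
        objective = fbc.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction("R_" + _to_sid(model.objective_id))
        flux_obj.setCoefficient(1.0)
        fbc.setActiveObjectiveId("obj")

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(document, str(path)):
        raise IOError(f"could not write SBML to {path!r}")


def _gpr_to_fbc_infix(rule: GprRule) -> str:
    def render(node):
        kind = node[0]
        if kind == "gene":
            return node[1]
        joiner = f" {kind} "
        return "(" + joiner.join(render(child) for child in node[1]) + ")"

    return render(rule.tree)


def read_sbml(path) -> MetabolicModel:
    """Read an SBML L3+FBC (or COBRA-notes style) model file."""
    import libsbml

    document = libsbml.readSBMLFromFile(str(path))
    if document.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise IOError(
            f"unreadable SBML file {path!r}: "
            + document.getErrorLog().toString()
        )
    sbml_model = document.getModel()
    if sbml_model is None:
        raise IOError(f"SBML file {path!r} contains no model")

    compartments = {}
    for i in range(sbml_model.getNumCompartments()):
        comp = sbml_model.getCompartment(i)
        compartments[comp.getId()] = comp.getName() or comp.getId()
    if not compartments:
        compartments = dict(DEFAULT_COMPARTMENTS)
    model = MetabolicModel(
        id=sbml_model.getId() or "model",
        name=sbml_model.getName() or "",
        compartments=compartments,
    )

    species_to_native = {}
    for i in range(sbml_model.getNumSpecies()):
        species = sbml_model.getSpecies(i)
        native = _strip_prefix(species.getId(), "M_")
        species_to_native[species.getId()] = native
        splug = species.getPlugin("fbc")
        formula = None
        charge = None
        if splug is not None:
            if splug.isSetChemicalFormula():
                formula = splug.getChemicalFormula()
            if splug.isSetCharge():
                charge = splug.getCharge()
        model.add_metabolite(
            Metabolite(
                id=native,
                name=species.getName() or native,
                compartment=species.getCompartment(),
                formula=formula,
                charge=charge,
            )
        )

    gene_label = {}
    fbc = sbml_model.getPlugin("fbc")
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or _strip_prefix(gp.getId(), "G_")

    parameters = {}
    for i in range(sbml_model.getNumParameters()):
        param = sbml_model.getParameter(i)
        parameters[param.getId()] = param.getValue()

    for i in range(sbml_model.getNumReactions()):
        sbml_rxn = sbml_model.getReaction(i)
        native_id = _strip_prefix(sbml_rxn.getId(), "R_")
        stoich = {}
        for j in range(sbml_rxn.getNumReactants()):
            ref = sbml_rxn.getReactant(j)
            met = species_to_native[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) - ref.getStoichiometry()
        for j in range(sbml_rxn.getNumProducts()):
            ref = sbml_rxn.getProduct(j)
            met = species_to_native[ref.getSpecies()]
            stoich[met] = stoich.get(met, 0.0) + ref.getStoichiometry()
        rplug = sbml_rxn.getPlugin("fbc")
        lo = hi = None
        gpr = GprRule("")
        if rplug is not None:
            if rplug.isSetLowerFluxBound():
                lo = parameters.get(rplug.getLowerFluxBound())
            if rplug.isSetUpperFluxBound():
                hi = parameters.get(rplug.getUpperFluxBound())
            assoc = rplug.getGeneProductAssociation()
            if assoc is not None:
                gpr = GprRule(_fbc_association_to_infix(assoc.getAssociation(), gene_label))
        if lo is None:
            lo = -UNBOUNDED if sbml_rxn.getReversible() else 0.0
            logger.warning(
                "reaction %s lacks a lower bound; default %g applied", native_id, lo
            )
        if hi is None:
            hi = UNBOUNDED
            logger.warning(
                "reaction %s lacks an upper bound; default %g applied", native_id, hi
            )
        subsystem, rtype = _parse_notes(sbml_rxn)
        model.add_reaction(
            Reaction(
                id=native_id,
                name=sbml_rxn.getName() or native_id,
                stoichiometry=stoich,
                lower_bound=float(lo),
                upper_bound=float(hi),
                subsystem=subsystem,
                rtype=rtype or _infer_rtype_sbml(model, stoich),
                gpr=gpr,
            )
        )

    if fbc is not None:
        objective = fbc.getActiveObjective()
        if objective is not None and objective.getNumFluxObjectives() > 0:
            rid = objective.getFluxObjective(0).getReaction()
            model.objective_id = _strip_prefix(rid, "R_")
    return model


def _strip_prefix(sid: str, prefix: str) -> str:
    raw = sid[len(prefix):] if sid.startswith(prefix) else sid
    # undo the bijective mangling of the compartment-suffix pattern
    m = re.fullmatch(r"([A-Za-z0-9_]+?)__([a-z0-9]+)__", raw)
    if m:
        return f"{m.group(1)}[{m.group(2)}]"
    return raw


def _parse_notes(sbml_rxn):
    subsystem, rtype = "", ""
    if sbml_rxn.isSetNotes():
        text = sbml_rxn.getNotesString()
        m = re.search(r"SUBSYSTEM:\s*([^<]*)", text)
        if m:
            subsystem = m.group(1).strip()
        m = re.search(r"RTYPE:\s*([^<]*)", text)
        if m:
            rtype = m.group(1).strip()
    return subsystem, rtype


def _infer_rtype_sbml(model: MetabolicModel, stoich: dict) -> str:
    comps = {model.metabolite(met_id).compartment for met_id in stoich}
    names = {model.compartments.get(c, "") for c in comps}
    if len(stoich) == 1 and names == {"extracellular"}:
        return "exchange"
    if len(comps) > 1:
        return "transport"
    return "biochemical"


def _fbc_association_to_infix(node, gene_label) -> str:
    import libsbml

    if node is None:
        return ""
    if isinstance(node, libsbml.GeneProductRef):
        ref = node.getGeneProduct()
        return gene_label.get(ref, _strip_prefix(ref, "G_"))
    if isinstance(node, libsbml.FbcAnd):
        parts = [
            _fbc_association_to_infix(node.getAssociation(i), gene_label)
            for i in range(node.getNumAssociations())
        ]
        return "(" + " and ".join(parts) + ")"
    if isinstance(node, libsbml.FbcOr):
        parts = [
            _fbc_association_to_infix(node.getAssociation(i), gene_label)
            for i in range(node.getNumAssociations())
        ]
        return "(" + " or ".join(parts) + ")"
    raise ModelStructureError(f"unsupported FBC association node {node!r}")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------


def _fmt(value) -> str:
    if value is None:
        return ""
    return f"{value:.6g}"


def write_flux_table(result, path) -> None:
    """One row per reaction; columns depend on the result type.

    Accepts a FluxDistribution (columns: reaction, flux), an FVAResult
    (reaction, min_flux, max_flux) or a DifferentialFluxReport (reaction,
    flux_A, flux_B, abs_change, changed). Floats at 6 significant digits.
    """
    from .cofactors import DifferentialFluxReport
    from .fba import FluxDistribution, FVAResult

    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        if isinstance(result, FluxDistribution):
            writer.writerow(["reaction", "flux"])
            for rid in result.fluxes:
                writer.writerow([rid, _fmt(result.fluxes[rid])])
        elif isinstance(result, FVAResult):
            writer.writerow(["reaction", "min_flux", "max_flux"])
            for rid, (lo, hi) in result.ranges.items():
                writer.writerow([rid, _fmt(lo), _fmt(hi)])
        elif isinstance(result, DifferentialFluxReport):
            changed = result.changed
            writer.writerow(
                [
                    "reaction",
                    f"flux_{result.condition_a}",
                    f"flux_{result.condition_b}",
                    "abs_change",
                    "changed",
                ]
            )
            for rid, (fa, fb, delta) in result.rows.items():
                writer.writerow(
                    [rid, _fmt(fa), _fmt(fb), _fmt(delta), int(rid in changed)]
                )
        else:
            raise TypeError(f"cannot serialize result of type {type(result)!r}")
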