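"""Assembly of a biomass reaction from macromolecular composition data.

The biomass equation drains six macromolecular components — protein, DNA,
RNA, lipid, cell wall and a small-molecule pool — as monomer metabolites in
proportion to their mass fractions, plus a growth-associated ATP
maintenance (GAM) hydrolysis cycle. Non-growth maintenance (NGAM) is a
separate pinned ATP-hydrolysis reaction.

The shipped default composition in :mod:`oleaflux.synthetic` is a
literature-typical fungal composition, not any particular organism's
measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .core import MetabolicModel, Metabolite, Reaction

COMPONENTS = ("protein", "dna", "rna", "lipid", "cell_wall", "small_pool")

FRACTION_TOL = 1e-6


class CompositionError(ValueError):
    pass


@dataclass
class BiomassComposition:
    """Mass fractions (g/gDW) per component plus monomer weight fractions.

    ``monomer_fractions[component]`` maps monomer metabolite id -> weight
    fraction within the component; each component's fractions must sum to 1.
    GAM is in mmol ATP per gDW biomass, NGAM in mmol ATP gDW^-1 h^-1.
    """

    fractions: dict
    monomer_fractions: dict
    gam: float = 0.0
    ngam: float = 0.0

    def validate(self, normalize: bool = False) -> "BiomassComposition":
        fr = dict(self.fractions)
        unknown = set(fr) - set(COMPONENTS)
        if unknown:
            raise CompositionError(f"unknown components: {sorted(unknown)}")
        if any(v < 0 for v in fr.values()):
            raise CompositionError("component fractions must be >= 0")
        total = sum(fr.values())
        if abs(total - 1.0) > FRACTION_TOL:
            if not normalize:
                raise CompositionError(
                    f"component fractions sum to {total}, not 1 "
                    "(pass normalize=True to rescale)"
                )
            fr = {k: v / total for k, v in fr.items()}
        mono = {}
        for comp, parts in self.monomer_fractions.items():
            sub_total = sum(parts.values())
            if abs(sub_total - 1.0) > FRACTION_TOL:
                if not normalize:
                    raise CompositionError(
                        f"monomer fractions of {comp!r} sum to {sub_total}, not 1"
                    )
                parts = {k: v / sub_total for k, v in parts.items()}
            mono[comp] = dict(parts)
        return BiomassComposition(fr, mono, self.gam, self.ngam)


def build_biomass_reaction(
    composition: BiomassComposition,
    monomer_molar_masses: Mapping[str, float],
    reaction_id: str = "biomass",
    biomass_metabolite: Optional[str] = None,
    energy_metabolites: Optional[Mapping[str, str]] = None,
    normalize: bool = False,
) -> Reaction:
    """Biomass reaction draining (fraction x monomer fraction)/M x 1000 mmol
    of each monomer per gDW, plus the GAM ATP-hydrolysis cycle.

    ``monomer_molar_masses`` is in g/mol; coefficients come out in
    mmol/gDW, so one unit of biomass flux (h^-1) drains exactly 1 g of
    monomer mass per gDW per hour. ``energy_metabolites`` names the atp /
    h2o / adp / pi / h species used by the GAM cycle (defaults
    ``atp[c]`` etc.).
    """
    comp = composition.validate(normalize=normalize)
    energy = dict(
        atp="atp[c]", h2o="h2o[c]", adp="adp[c]", pi="pi[c]", h="h[c]"
    )
    if energy_metabolites:
        energy.update(energy_metabolites)
    stoich: dict[str, float] = {}
    for component, comp_fraction in comp.fractions.items():
        if comp_fraction == 0:
            continue
        monomers = comp.monomer_fractions.get(component)
        if not monomers:
            raise CompositionError(
                f"component {component!r} has mass but no monomer fractions"
            )
        for met_id, weight_fraction in monomers.items():
            if weight_fraction == 0:
                continue
            molar_mass = monomer_molar_masses.get(met_id)
            if molar_mass is None or molar_mass <= 0:
                raise CompositionError(
                    f"monomer {met_id!r} needs a positive molar mass"
                )
            mmol_per_gdw = comp_fraction * weight_fraction / molar_mass * 1000.0
            # 12 decimal places: far inside the 1e-6 mass-balance tolerance
            # and exactly representable by SBML's 15-significant-digit doubles
            stoich[met_id] = round(stoich.get(met_id, 0.0) - mmol_per_gdw, 12)
    if comp.gam < 0:
        raise CompositionError("GAM must be >= 0")
    if comp.gam > 0:
        stoich[energy["atp"]] = stoich.get(energy["atp"], 0.0) - comp.gam
        stoich[energy["h2o"]] = stoich.get(energy["h2o"], 0.0) - comp.gam
        stoich[energy["adp"]] = stoich.get(energy["adp"], 0.0) + comp.gam
        stoich[energy["pi"]] = stoich.get(energy["pi"], 0.0) + comp.gam
        stoich[energy["h"]] = stoich.get(energy["h"], 0.0) + comp.gam
    if biomass_metabolite is not None:
        stoich[biomass_metabolite] = stoich.get(biomass_metabolite, 0.0) + 1.0
    return Reaction(
        id=reaction_id,
        name="biomass assembly",
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        rtype="biochemical",
        subsystem="Biomass",
    )


def monomer_mass_drain(
    reaction: Reaction,
    monomer_molar_masses: Mapping[str, float],
) -> float:
    """Grams of monomer mass drained per unit biomass flux (GAM excluded).

    Only metabolites present in ``monomer_molar_masses`` are counted, so
    the mass-neutral ATP-hydrolysis cycle does not contribute.
    """
    total = 0.0
    for met_id, coef in reaction.stoichiometry.items():
        molar_mass = monomer_molar_masses.get(met_id)
        if molar_mass is not None and coef < 0:
            total += -coef * molar_mass / 1000.0
    return total


def add_ngam(
    model: MetabolicModel,
    ngam_value: float,
    maintenance_id: str = "ATPM",
    energy_metabolites: Optional[Mapping[str, str]] = None,
) -> MetabolicModel:
    """Copy of the model with the ATP maintenance flux pinned to NGAM.

    If the maintenance reaction is absent an ATP-hydrolysis reaction is
    added using the given energy metabolite ids.
    """
    if ngam_value < 0:
        raise CompositionError("NGAM must be >= 0")
    energy = dict(
        atp="atp[c]", h2o="h2o[c]", adp="adp[c]", pi="pi[c]", h="h[c]"
    )
    if energy_metabolites:
        energy.update(energy_metabolites)
    new = model.copy()
    if not new.has_reaction(maintenance_id):
        for met_id in energy.values():
            if not new.has_metabolite(met_id):
                raise CompositionError(
                    f"cannot add maintenance reaction: metabolite {met_id!r} "
                    "is missing"
                )
        new.add_reaction(
            Reaction(
                id=maintenance_id,
                name="non-growth ATP maintenance",
                # neutral-formula hydrolysis: ATP + H2O -> ADP + Pi is
                # elementally closed without a free proton
                stoichiometry={
                    energy["atp"]: -1.0,
                    energy["h2o"]: -1.0,
                    energy["adp"]: 1.0,
                    energy["pi"]: 1.0,
                },
                rtype="biochemical",
                subsystem="Maintenance",
            )
        )
    rxn = new.reaction(maintenance_id)
    rxn.lower_bound = ngam_value
    rxn.upper_bound = ngam_value
    return new
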