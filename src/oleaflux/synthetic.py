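"""Deterministic synthetic test models.

``generate_mini_alpina`` builds a curated, fully specified oleaginous-fungus
model ("mini-alpina") of ~160 reactions across four compartments
(extracellular, cytosol, mitochondrion, peroxisome). It carries:

* glucose / glycerol / ethanol / acetate / lactate / rhamnose carbon entry
  routes and an optional catabolically orphaned sugar,
* lumped glycolysis, gluconeogenesis, oxidative and non-oxidative pentose
  phosphate reactions, the citrate/malate shuttle, a mitochondrial TCA +
  respiration block and a peroxisomal glyoxylate block,
* cytosolic malic enzyme as an NADPH source next to the two oxidative PPP
  dehydrogenases,
* the omega-6 elongation/desaturation chain from palmitate to free
  arachidonate (with an optional omega-3 branch to eicosapentaenoate), each
  desaturase/elongase step explicit and gene-tagged,
* nitrate -> nitrite -> ammonia assimilation, sulfate assimilation, lumped
  synthesis reactions for all twenty amino acids plus their uptake
  exchanges, and a six-component biomass equation.

Every metabolite with a known formula is elementally audited at build time:
reactions are written with their C/N/P/S skeleton and the builder closes
oxygen and hydrogen exactly by adding water/protons. All coefficients are
exact decimals so repeated generation is bit-identical.

``generate_random_viable_model`` embeds a guaranteed uptake->biomass
backbone and decorates it with seeded random reactions (which may create
gaps) for property testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .biomass import BiomassComposition, add_ngam, build_biomass_reaction
from .core import (
    GprRule,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_formula,
)
from .fba import Medium


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mini-alpina
# ---------------------------------------------------------------------------


@dataclass
class MiniAlpinaSpec:
    """Toggles and parameters for the curated synthetic model."""

    include_omega3: bool = True
    include_orphan_sugar: bool = True
    oxygen_per_desaturation: float = 1.0
    nadph_per_elongation: float = 2.0
    me_present: bool = True
    ppp_present: bool = True
    delta5_present: bool = True
    require_ara: bool = True
    gam: float = 30.0
    ngam: float = 1.0
    glucose_uptake: float = 0.8
    amino_acid_uptake: float = 0.01
    seed: int = 0

    def validate(self):
        if self.require_ara and not self.delta5_present:
            raise SpecError(
                "ARA production requested but the delta-5 desaturase is "
                "disabled — the chain cannot reach arachidonate"
            )
        if self.oxygen_per_desaturation <= 0:
            raise SpecError("oxygen_per_desaturation must be > 0")
        if self.nadph_per_elongation < 0:
            raise SpecError("nadph_per_elongation must be >= 0")
        if self.gam < 0 or self.ngam < 0:
            raise SpecError("GAM/NGAM must be >= 0")


@dataclass
class GroundTruth:
    """Construction facts recorded by the generator for test oracles."""

    biomass_reaction: str
    maintenance_reaction: str
    ara_exchange: str
    epa_exchange: Optional[str]
    glucose_exchange: str
    oxygen_exchange: str
    nitrate_exchange: str
    me_reaction: Optional[str]
    me_gene: Optional[str]
    ppp_reactions: list
    nadph_reactions: list
    nadph_producers: list
    nitrate_reductase_gene: str
    nitrite_reductase_gene: str
    amino_acid_synthesis_genes: dict  # aa -> gene id
    amino_acid_exchanges: dict  # aa -> exchange id
    expected_mg_essential_genes: list
    rhamnose_lyase_reaction: str
    orphan_sugar_exchange: Optional[str]
    oxygen_optimum_window: tuple  # (lo, hi) bracketing the ARA-optimal uptake

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["oxygen_optimum_window"] = list(d["oxygen_optimum_window"])
        return d


#: amino acid -> (formula, molar mass g/mol)
AA_TABLE = {
    "ala": ("C3H7NO2", 89.09),
    "arg": ("C6H14N4O2", 174.20),
    "asn": ("C4H8N2O3", 132.12),
    "asp": ("C4H7NO4", 133.10),
    "cys": ("C3H7NO2S", 121.16),
    "gln": ("C5H10N2O3", 146.15),
    "glu": ("C5H9NO4", 147.13),
    "gly": ("C2H5NO2", 75.07),
    "his": ("C6H9N3O2", 155.15),
    "ile": ("C6H13NO2", 131.17),
    "leu": ("C6H13NO2", 131.17),
    "lys": ("C6H14N2O2", 146.19),
    "met": ("C5H11NO2S", 149.21),
    "phe": ("C9H11NO2", 165.19),
    "pro": ("C5H9NO2", 115.13),
    "ser": ("C3H7NO3", 105.09),
    "thr": ("C4H9NO3", 119.12),
    "trp": ("C11H12N2O2", 204.23),
    "tyr": ("C9H11NO3", 181.19),
    "val": ("C5H11NO2", 117.15),
}

_COA = {"C": 21, "H": 36, "N": 7, "O": 16, "P": 3, "S": 1}


def _acyl_coa_formula(n_carbons: int, n_double_bonds: int) -> str:
    """Formula of a fatty acyl-CoA thioester (acid + CoA - H2O)."""
    c = _COA["C"] + n_carbons
    h = _COA["H"] + (2 * n_carbons - 2 * n_double_bonds) - 2
    o = _COA["O"] + 1
    return f"C{c}H{h}N{_COA['N']}O{o}P{_COA['P']}S{_COA['S']}"


class _Builder:
    """Assembles the model, auto-closing O/H balances with water/protons."""

    def __init__(self, model_id: str):
        self.model = MetabolicModel(id=model_id)

    def met(self, met_id, name="", formula=None, charge=None):
        compartment = met_id[met_id.rindex("[") + 1 : -1]
        self.model.add_metabolite(
            Metabolite(met_id, name or met_id, compartment, formula, charge)
        )

    def rxn(
        self,
        rxn_id,
        stoich,
        lb,
        ub,
        rtype="biochemical",
        subsystem="",
        gpr="",
        name="",
        balance=True,
    ):
        comp = None
        if rtype == "biochemical" and balance:
            comps = {
                self.model.metabolite(m).compartment for m in stoich
            }
            comp = comps.pop() if len(comps) == 1 else None
            stoich = self._close_oh(rxn_id, dict(stoich), comp)
        self.model.add_reaction(
            Reaction(
                id=rxn_id,
                name=name or rxn_id,
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                rtype=rtype,
                subsystem=subsystem,
                gpr=GprRule(gpr),
            )
        )

    def _close_oh(self, rxn_id, stoich, compartment):
        """Add h2o/h to zero O and H; assert C, N, P, S already balance."""
        if compartment is None:
            return stoich
        net: dict[str, float] = {}
        for met_id, coef in stoich.items():
            formula = self.model.metabolite(met_id).formula
            if formula is None:
                return stoich  # unaudited lump
            for el, count in parse_formula(formula).items():
                net[el] = net.get(el, 0.0) + coef * count
        for el in ("C", "N", "P", "S"):
            if abs(net.get(el, 0.0)) > 1e-9:
                raise AssertionError(
                    f"{rxn_id}: element {el} off by {net[el]:+g}"
                )
        h2o = f"h2o[{compartment}]"
        h = f"h[{compartment}]"
        oxygen = net.get("O", 0.0)
        if abs(oxygen) > 1e-9:
            stoich[h2o] = stoich.get(h2o, 0.0) - oxygen
        hydrogen = net.get("H", 0.0) - 2.0 * oxygen
        if abs(hydrogen) > 1e-9:
            stoich[h] = stoich.get(h, 0.0) - hydrogen
        stoich = {m: c for m, c in stoich.items() if abs(c) > 1e-12}
        return stoich


def _add_small_molecules(b: _Builder, spec: MiniAlpinaSpec):
    # extracellular
    ext = [
        ("glc[e]", "D-glucose", "C6H12O6"),
        ("glyc[e]", "glycerol", "C3H8O3"),
        ("etoh[e]", "ethanol", "C2H6O"),
        ("ac[e]", "acetate", "C2H4O2"),
        ("llac[e]", "L-lactate", "C3H6O3"),
        ("rha[e]", "L-rhamnose", "C6H12O5"),
        ("o2[e]", "oxygen", "O2"),
        ("co2[e]", "carbon dioxide", "CO2"),
        ("h2o[e]", "water", "H2O"),
        ("h[e]", "proton", "H"),
        ("pi[e]", "phosphate", "H3O4P"),
        ("so4[e]", "sulfate", "H2O4S"),
        ("no3[e]", "nitrate", "HNO3"),
        ("nh3[e]", "ammonia", "H3N"),
        ("ara[e]", "arachidonate", "C20H32O2"),
    ]
    if spec.include_omega3:
        ext.append(("epa[e]", "eicosapentaenoate", "C20H30O2"))
    if spec.include_orphan_sugar:
        ext.append(("orph[e]", "orphan sugar", "C6H12O6"))
    for met_id, name, formula in ext:
        b.met(met_id, name, formula)
    # cytosol
    cyt = [
        ("glc[c]", "D-glucose", "C6H12O6"),
        ("g6p[c]", "D-glucose 6-phosphate", "C6H13O9P"),
        ("pg6[c]", "6-phospho-D-gluconate", "C6H13O10P"),
        ("ru5p[c]", "D-ribulose 5-phosphate", "C5H11O8P"),
        ("e4p[c]", "D-erythrose 4-phosphate", "C4H9O7P"),
        ("dhap[c]", "glycerone phosphate", "C3H7O6P"),
        ("pep[c]", "phosphoenolpyruvate", "C3H5O6P"),
        ("pyr[c]", "pyruvate", "C3H4O3"),
        ("oaa[c]", "oxaloacetate", "C4H4O5"),
        ("mal[c]", "(S)-malate", "C4H6O5"),
        ("cit[c]", "citrate", "C6H8O7"),
        ("akg[c]", "2-oxoglutarate", "C5H6O5"),
        ("glyc[c]", "glycerol", "C3H8O3"),
        ("etoh[c]", "ethanol", "C2H6O"),
        ("acald[c]", "acetaldehyde", "C2H4O"),
        ("ac[c]", "acetate", "C2H4O2"),
        ("llac[c]", "L-lactate", "C3H6O3"),
        ("rha[c]", "L-rhamnose", "C6H12O5"),
        ("rhap[c]", "L-rhamnulose 1-phosphate", "C6H13O8P"),
        ("lald[c]", "L-lactaldehyde", "C3H6O2"),
        ("coa[c]", "coenzyme A", "C21H36N7O16P3S"),
        ("accoa[c]", "acetyl-CoA", "C23H38N7O17P3S"),
        ("malcoa[c]", "malonyl-CoA", "C24H38N7O19P3S"),
        ("atp[c]", "ATP", "C10H16N5O13P3"),
        ("adp[c]", "ADP", "C10H15N5O10P2"),
        ("amp[c]", "AMP", "C10H14N5O7P"),
        ("pi[c]", "phosphate", "H3O4P"),
        ("ppi[c]", "diphosphate", "H4O7P2"),
        ("nad[c]", "NAD+", "C21H27N7O14P2"),
        ("nadh[c]", "NADH", "C21H28N7O14P2"),
        ("nadp[c]", "NADP+", "C21H28N7O17P3"),
        ("nadph[c]", "NADPH", "C21H29N7O17P3"),
        ("o2[c]", "oxygen", "O2"),
        ("co2[c]", "carbon dioxide", "CO2"),
        ("h2o[c]", "water", "H2O"),
        ("h[c]", "proton", "H"),
        ("so4[c]", "sulfate", "H2O4S"),
        ("h2s[c]", "hydrogen sulfide", "H2S"),
        ("no3[c]", "nitrate", "HNO3"),
        ("no2[c]", "nitrite", "HNO2"),
        ("nh3[c]", "ammonia", "H3N"),
        ("c160[c]", "palmitate", "C16H32O2"),
        ("ara[c]", "arachidonate", "C20H32O2"),
        ("glucan[c]", "cell-wall glucan unit", "C6H10O5"),
        ("ntp[c]", "NTP pool", None),
        ("dntp[c]", "dNTP pool", None),
    ]
    if spec.include_orphan_sugar:
        cyt.append(("orph[c]", "orphan sugar", "C6H12O6"))
    if spec.include_omega3:
        cyt.append(("epa[c]", "eicosapentaenoate", "C20H30O2"))
    for met_id, name, formula in cyt:
        b.met(met_id, name, formula)
    for aa, (formula, _) in AA_TABLE.items():
        b.met(f"{aa}[c]", f"L-{aa}", formula)
        b.met(f"{aa}[e]", f"L-{aa}", formula)
    # acyl-CoAs of the PUFA chain
    chain = [
        ("c160coa", 16, 0, "hexadecanoyl-CoA"),
        ("c180coa", 18, 0, "octadecanoyl-CoA"),
        ("c181coa", 18, 1, "octadecenoyl-CoA"),
        ("c182coa", 18, 2, "linoleoyl-CoA"),
        ("c183n6coa", 18, 3, "gamma-linolenoyl-CoA"),
        ("c203n6coa", 20, 3, "dihomo-gamma-linolenoyl-CoA"),
        ("c204n6coa", 20, 4, "arachidonyl-CoA"),
    ]
    if spec.include_omega3:
        chain += [
            ("c183n3coa", 18, 3, "alpha-linolenoyl-CoA"),
            ("c184n3coa", 18, 4, "stearidonoyl-CoA"),
            ("c204n3coa", 20, 4, "icosatrienoyl-CoA(n-3)"),
            ("c205n3coa", 20, 5, "eicosapentaenoyl-CoA"),
        ]
    for base, n, d, name in chain:
        b.met(f"{base}[c]", name, _acyl_coa_formula(n, d))
    # mitochondrion
    for met_id, name, formula in [
        ("pyr[m]", "pyruvate", "C3H4O3"),
        ("oaa[m]", "oxaloacetate", "C4H4O5"),
        ("mal[m]", "(S)-malate", "C4H6O5"),
        ("cit[m]", "citrate", "C6H8O7"),
        ("coa[m]", "coenzyme A", "C21H36N7O16P3S"),
        ("accoa[m]", "acetyl-CoA", "C23H38N7O17P3S"),
        ("atp[m]", "ATP", "C10H16N5O13P3"),
        ("adp[m]", "ADP", "C10H15N5O10P2"),
        ("pi[m]", "phosphate", "H3O4P"),
        ("nad[m]", "NAD+", "C21H27N7O14P2"),
        ("nadh[m]", "NADH", "C21H28N7O14P2"),
        ("o2[m]", "oxygen", "O2"),
        ("co2[m]", "carbon dioxide", "CO2"),
        ("h2o[m]", "water", "H2O"),
        ("h[m]", "proton", "H"),
    ]:
        b.met(met_id, name, formula)
    # peroxisome
    for met_id, name, formula in [
        ("accoa[x]", "acetyl-CoA", "C23H38N7O17P3S"),
        ("coa[x]", "coenzyme A", "C21H36N7O16P3S"),
        ("mal[x]", "(S)-malate", "C4H6O5"),
        ("nad[x]", "NAD+", "C21H27N7O14P2"),
        ("nadh[x]", "NADH", "C21H28N7O14P2"),
        ("o2[x]", "oxygen", "O2"),
        ("h2o[x]", "water", "H2O"),
        ("h[x]", "proton", "H"),
    ]:
        b.met(met_id, name, formula)


def _exchange(b: _Builder, met_base: str, lb=-1000.0, ub=1000.0):
    b.rxn(
        f"EX_{met_base}",
        {f"{met_base}[e]": -1.0},
        lb,
        ub,
        rtype="exchange",
        subsystem="Exchange",
    )


def _transport(b: _Builder, rxn_id, met_from, met_to, lb=-1000.0, ub=1000.0, gpr=""):
    b.rxn(
        rxn_id,
        {met_from: -1.0, met_to: 1.0},
        lb,
        ub,
        rtype="transport",
        subsystem="Transport",
        gpr=gpr,
    )


def default_biomass_composition(gam: float = 30.0, ngam: float = 1.0):
    """Literature-typical fungal macromolecular composition (not any
    particular organism's measured values) with its monomer molar masses."""
    protein_monomers = {f"{aa}[c]": 0.05 for aa in AA_TABLE}
    composition = BiomassComposition(
        fractions={
            "protein": 0.45,
            "dna": 0.015,
            "rna": 0.06,
            "lipid": 0.25,
            "cell_wall": 0.2,
            "small_pool": 0.025,
        },
        monomer_fractions={
            "protein": protein_monomers,
            "dna": {"dntp[c]": 1.0},
            "rna": {"ntp[c]": 1.0},
            "lipid": {"c160[c]": 0.9, "glyc[c]": 0.1},
            "cell_wall": {"glucan[c]": 1.0},
            "small_pool": {"atp[c]": 1.0},
        },
        gam=gam,
        ngam=ngam,
    )
    masses = {f"{aa}[c]": mass for aa, (_, mass) in AA_TABLE.items()}
    masses.update(
        {
            "dntp[c]": 490.0,
            "ntp[c]": 500.0,
            "c160[c]": 256.42,
            "glyc[c]": 92.09,
            "glucan[c]": 162.14,
            "atp[c]": 507.18,
        }
    )
    return composition, masses


def generate_mini_alpina(
    spec: Optional[MiniAlpinaSpec] = None,
) -> tuple[MetabolicModel, GroundTruth]:
    spec = spec or MiniAlpinaSpec()
    spec.validate()
    b = _Builder("mini_alpina")
    _add_small_molecules(b, spec)

    # ----- exchanges ------------------------------------------------------
    for base in [
        "glc",
        "glyc",
        "etoh",
        "ac",
        "llac",
        "rha",
        "o2",
        "co2",
        "h2o",
        "h",
        "pi",
        "so4",
        "no3",
        "nh3",
    ]:
        _exchange(b, base)
    _exchange(b, "ara", 0.0, 1000.0)  # product only
    if spec.include_omega3:
        _exchange(b, "epa", 0.0, 1000.0)
    if spec.include_orphan_sugar:
        _exchange(b, "orph")
    for aa in AA_TABLE:
        _exchange(b, aa)

    # ----- plasma-membrane transport -------------------------------------
    for base in [
        "glc",
        "glyc",
        "etoh",
        "ac",
        "llac",
        "rha",
        "o2",
        "co2",
        "h2o",
        "h",
        "pi",
        "so4",
        "no3",
        "nh3",
    ]:
        _transport(b, f"T_{base}", f"{base}[e]", f"{base}[c]")
    _transport(b, "T_ara", "ara[c]", "ara[e]", 0.0)
    if spec.include_omega3:
        _transport(b, "T_epa", "epa[c]", "epa[e]", 0.0)
    if spec.include_orphan_sugar:
        _transport(b, "T_orph", "orph[e]", "orph[c]")
    for aa in AA_TABLE:
        _transport(b, f"T_{aa}", f"{aa}[e]", f"{aa}[c]")

    # ----- central carbon (cytosol) --------------------------------------
    CH = "Carbohydrate metabolism"
    b.rxn("HEX", {"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1},
          0, 1000, subsystem=CH, gpr="g_hxk")
    b.rxn(
        "GLYC2",
        {"g6p[c]": -1, "nad[c]": -2, "pi[c]": -2, "adp[c]": -1,
         "pep[c]": 2, "nadh[c]": 2, "atp[c]": 1},
        0, 1000, subsystem=CH, gpr="g_gly1",
    )
    b.rxn("PYK", {"pep[c]": -1, "adp[c]": -1, "pyr[c]": 1, "atp[c]": 1},
          0, 1000, subsystem=CH, gpr="g_pyk")
    b.rxn(
        "GNG",
        {"pep[c]": -2, "nadh[c]": -2, "atp[c]": -1,
         "g6p[c]": 1, "nad[c]": 2, "adp[c]": 1, "pi[c]": 2},
        0, 1000, subsystem=CH, gpr="g_fbp",
    )
    if spec.ppp_present:
        b.rxn("PPP1", {"g6p[c]": -1, "nadp[c]": -1, "pg6[c]": 1, "nadph[c]": 1},
              0, 1000, subsystem=CH, gpr="g_zwf")
        b.rxn(
            "PPP2",
            {"pg6[c]": -1, "nadp[c]": -1, "ru5p[c]": 1, "co2[c]": 1,
             "nadph[c]": 1},
            0, 1000, subsystem=CH, gpr="g_gnd",
        )
    b.rxn("NONOX_E4P", {"ru5p[c]": -2, "e4p[c]": 1, "g6p[c]": 1},
          0, 1000, subsystem=CH, gpr="g_tkt")
    b.rxn("NONOX_R", {"ru5p[c]": -6, "g6p[c]": 5, "pi[c]": 1},
          0, 1000, subsystem=CH, gpr="g_tal")
    b.rxn("PC", {"pyr[c]": -1, "co2[c]": -1, "atp[c]": -1,
                 "oaa[c]": 1, "adp[c]": 1, "pi[c]": 1},
          0, 1000, subsystem=CH, gpr="g_pyc")
    b.rxn("MDHc", {"oaa[c]": -1, "nadh[c]": -1, "mal[c]": 1, "nad[c]": 1},
          -1000, 1000, subsystem=CH, gpr="g_mdh1")
    if spec.me_present:
        b.rxn("ME", {"mal[c]": -1, "nadp[c]": -1,
                     "pyr[c]": 1, "co2[c]": 1, "nadph[c]": 1},
              0, 1000, subsystem=CH, gpr="g_me")
    b.rxn("ACO_IDH", {"cit[c]": -1, "nad[c]": -1,
                      "akg[c]": 1, "co2[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=CH, gpr="g_idh")
    b.rxn("ACL", {"cit[c]": -1, "atp[c]": -1, "coa[c]": -1,
                  "accoa[c]": 1, "oaa[c]": 1, "adp[c]": 1, "pi[c]": 1},
          0, 1000, subsystem=CH, gpr="g_acl")
    b.rxn("PEPCK", {"oaa[c]": -1, "atp[c]": -1,
                    "pep[c]": 1, "co2[c]": 1, "adp[c]": 1},
          0, 1000, subsystem=CH, gpr="g_pck")

    # alternative carbon entries
    b.rxn("ADH", {"etoh[c]": -1, "nad[c]": -1, "acald[c]": 1, "nadh[c]": 1},
          -1000, 1000, subsystem=CH, gpr="g_adh")
    b.rxn("ALDH", {"acald[c]": -1, "nad[c]": -1, "ac[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=CH, gpr="g_aldh")
    b.rxn("ACS", {"ac[c]": -1, "atp[c]": -1, "coa[c]": -1,
                  "accoa[c]": 1, "amp[c]": 1, "ppi[c]": 1},
          0, 1000, subsystem=CH, gpr="g_acs")
    b.rxn("ADK", {"amp[c]": -1, "atp[c]": -1, "adp[c]": 2},
          -1000, 1000, subsystem=CH, gpr="g_adk")
    b.rxn("PPA", {"ppi[c]": -1, "pi[c]": 2},
          0, 1000, subsystem=CH, gpr="g_ppa")
    b.rxn("GLYCK", {"glyc[c]": -1, "atp[c]": -1, "nad[c]": -1,
                    "dhap[c]": 1, "adp[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=CH, gpr="g_glk")
    b.rxn("GLYC_SYN", {"dhap[c]": -1, "nadh[c]": -1,
                       "glyc[c]": 1, "nad[c]": 1, "pi[c]": 1},
          0, 1000, subsystem=CH, gpr="g_gpp")
    b.rxn("DHAP_PEP", {"dhap[c]": -1, "nad[c]": -1, "pi[c]": -1, "adp[c]": -1,
                       "pep[c]": 1, "nadh[c]": 1, "atp[c]": 1},
          -1000, 1000, subsystem=CH, gpr="g_tpi")
    b.rxn("RHAK", {"rha[c]": -1, "atp[c]": -1, "rhap[c]": 1, "adp[c]": 1},
          0, 1000, subsystem=CH, gpr="g_rhk")
    b.rxn("RHA_LYASE", {"rhap[c]": -1, "dhap[c]": 1, "lald[c]": 1},
          0, 1000, subsystem=CH, gpr="g_rhl")
    b.rxn("LALD_DH", {"lald[c]": -1, "nad[c]": -1, "llac[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=CH, gpr="g_ald2")
    b.rxn("LLD", {"llac[c]": -1, "nad[c]": -1, "pyr[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=CH, gpr="g_lld")

    # ----- mitochondrion --------------------------------------------------
    EN = "Energy metabolism"
    _transport(b, "T_pyr_m", "pyr[c]", "pyr[m]")
    _transport(b, "T_cit_m", "cit[m]", "cit[c]")
    _transport(b, "T_mal_m", "mal[c]", "mal[m]")
    _transport(b, "T_oaa_m", "oaa[m]", "oaa[c]")
    _transport(b, "T_o2_m", "o2[c]", "o2[m]")
    _transport(b, "T_co2_m", "co2[m]", "co2[c]")
    _transport(b, "T_h2o_m", "h2o[c]", "h2o[m]")
    _transport(b, "T_h_m", "h[c]", "h[m]")
    _transport(b, "T_pi_m", "pi[c]", "pi[m]")
    _transport(b, "T_adp_m", "adp[c]", "adp[m]")
    _transport(b, "T_nad_m", "nad[c]", "nad[m]")
    _transport(b, "T_coa_m", "coa[c]", "coa[m]")
    b.rxn("ANT", {"atp[m]": -1, "adp[c]": -1, "atp[c]": 1, "adp[m]": 1},
          0, 1000, rtype="transport", subsystem="Transport", gpr="g_ant")
    b.rxn("PDHm", {"pyr[m]": -1, "coa[m]": -1, "nad[m]": -1,
                   "accoa[m]": 1, "co2[m]": 1, "nadh[m]": 1},
          0, 1000, subsystem=EN, gpr="g_pdh1 and g_pdh2 and g_pdh3")
    b.rxn("CSm", {"accoa[m]": -1, "oaa[m]": -1, "cit[m]": 1, "coa[m]": 1},
          0, 1000, subsystem=EN, gpr="g_cs")
    b.rxn("MDHm", {"mal[m]": -1, "nad[m]": -1, "oaa[m]": 1, "nadh[m]": 1},
          -1000, 1000, subsystem=EN, gpr="g_mdh2")
    b.rxn("TCAm", {"accoa[m]": -1, "nad[m]": -4,
                   "co2[m]": 2, "nadh[m]": 4, "coa[m]": 1},
          0, 1000, subsystem=EN, gpr="g_tca")
    b.rxn("ETC", {"nadh[m]": -1, "o2[m]": -0.5, "adp[m]": -2, "pi[m]": -2,
                  "nad[m]": 1, "atp[m]": 2},
          0, 1000, subsystem=EN, gpr="g_etc")
    b.rxn("AOXm", {"nadh[m]": -1, "o2[m]": -0.5, "nad[m]": 1},
          0, 1000, subsystem=EN, gpr="g_aox")

    # ----- peroxisome (glyoxylate block) ---------------------------------
    _transport(b, "T_accoa_x", "accoa[c]", "accoa[x]")
    _transport(b, "T_coa_x", "coa[x]", "coa[c]")
    _transport(b, "T_mal_x", "mal[x]", "mal[c]")
    _transport(b, "T_o2_x", "o2[c]", "o2[x]")
    _transport(b, "T_h2o_x", "h2o[c]", "h2o[x]")
    _transport(b, "T_h_x", "h[c]", "h[x]")
    _transport(b, "T_nad_x", "nad[c]", "nad[x]")
    b.rxn("GLYOXx", {"accoa[x]": -2, "nad[x]": -1,
                     "mal[x]": 1, "coa[x]": 2, "nadh[x]": 1},
          0, 1000, subsystem=EN, gpr="g_icl and g_mls")
    b.rxn("PEROXx", {"nadh[x]": -1, "o2[x]": -0.5, "nad[x]": 1},
          0, 1000, subsystem=EN, gpr="g_pox")

    # ----- nitrogen and sulfur assimilation ------------------------------
    AA = "Amino acid metabolism"
    b.rxn("NR", {"no3[c]": -1, "nadh[c]": -1, "no2[c]": 1, "nad[c]": 1},
          0, 1000, subsystem=AA, gpr="g_nr")
    b.rxn("NIR", {"no2[c]": -1, "nadph[c]": -3, "nh3[c]": 1, "nadp[c]": 3},
          0, 1000, subsystem=AA, gpr="g_nir")
    b.rxn("SUAS", {"so4[c]": -1, "atp[c]": -1, "nadph[c]": -4,
                   "h2s[c]": 1, "adp[c]": 1, "pi[c]": 1, "nadp[c]": 4},
          0, 1000, subsystem=EN, gpr="g_sua")

    # ----- amino acid metabolism -----------------------------------------
    b.rxn("GDH_NADP", {"akg[c]": -1, "nh3[c]": -1, "nadph[c]": -1,
                       "glu[c]": 1, "nadp[c]": 1},
          0, 1000, subsystem=AA, gpr="g_gdh1")
    b.rxn("GDH_NAD", {"glu[c]": -1, "nad[c]": -1,
                      "akg[c]": 1, "nh3[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=AA, gpr="g_gdh2")
    b.rxn("AST", {"oaa[c]": -1, "glu[c]": -1, "asp[c]": 1, "akg[c]": 1},
          -1000, 1000, subsystem=AA, gpr="g_ast")
    syn = {
        "ala": ({"pyr[c]": -1, "glu[c]": -1, "ala[c]": 1, "akg[c]": 1}, "g_ala1"),
        "arg": ({"glu[c]": -1, "co2[c]": -1, "nh3[c]": -3, "atp[c]": -4,
                 "arg[c]": 1, "adp[c]": 4, "pi[c]": 4}, "g_arg1"),
        "asn": ({"asp[c]": -1, "nh3[c]": -1, "atp[c]": -1,
                 "asn[c]": 1, "adp[c]": 1, "pi[c]": 1}, "g_asn1"),
        "cys": ({"ser[c]": -1, "h2s[c]": -1, "cys[c]": 1}, "g_cys1"),
        "gln": ({"glu[c]": -1, "nh3[c]": -1, "atp[c]": -1,
                 "gln[c]": 1, "adp[c]": 1, "pi[c]": 1}, "g_gln1"),
        "gly": ({"ser[c]": -1, "nad[c]": -1,
                 "gly[c]": 1, "co2[c]": 1, "nadh[c]": 1}, "g_gly2"),
        "his": ({"ru5p[c]": -1, "co2[c]": -1, "nh3[c]": -3, "atp[c]": -2,
                 "nad[c]": -3, "his[c]": 1, "adp[c]": 2, "pi[c]": 3,
                 "nadh[c]": 3}, "g_his1"),
        "ile": ({"pyr[c]": -2, "glu[c]": -1, "nadph[c]": -2,
                 "ile[c]": 1, "akg[c]": 1, "nadp[c]": 2}, "g_ile1"),
        "leu": ({"pyr[c]": -2, "accoa[c]": -1, "glu[c]": -1, "nad[c]": -1,
                 "leu[c]": 1, "akg[c]": 1, "co2[c]": 2, "coa[c]": 1,
                 "nadh[c]": 1}, "g_leu1"),
        "lys": ({"accoa[c]": -1, "glu[c]": -1, "nh3[c]": -1, "nadph[c]": -2,
                 "atp[c]": -1, "lys[c]": 1, "co2[c]": 1, "coa[c]": 1,
                 "nadp[c]": 2, "adp[c]": 1, "pi[c]": 1}, "g_lys1"),
        "met": ({"asp[c]": -1, "co2[c]": -1, "h2s[c]": -1, "nadph[c]": -4,
                 "atp[c]": -1, "met[c]": 1, "nadp[c]": 4, "adp[c]": 1,
                 "pi[c]": 1}, "g_met1"),
        "phe": ({"pep[c]": -2, "e4p[c]": -1, "glu[c]": -1, "nadph[c]": -1,
                 "atp[c]": -1, "phe[c]": 1, "akg[c]": 1, "co2[c]": 1,
                 "nadp[c]": 1, "adp[c]": 1, "pi[c]": 4}, "g_phe1"),
        "pro": ({"glu[c]": -1, "atp[c]": -1, "nadph[c]": -2,
                 "pro[c]": 1, "adp[c]": 1, "pi[c]": 1, "nadp[c]": 2},
                "g_pro1"),
        "ser": ({"pep[c]": -1, "glu[c]": -1, "nad[c]": -1,
                 "ser[c]": 1, "akg[c]": 1, "nadh[c]": 1, "pi[c]": 1},
                "g_ser1"),
        "thr": ({"asp[c]": -1, "atp[c]": -2, "nadph[c]": -2,
                 "thr[c]": 1, "adp[c]": 2, "pi[c]": 2, "nadp[c]": 2},
                "g_thr1"),
        "trp": ({"pep[c]": -2, "e4p[c]": -1, "ser[c]": -1, "nh3[c]": -1,
                 "atp[c]": -1, "trp[c]": 1, "co2[c]": 2, "adp[c]": 1,
                 "pi[c]": 4}, "g_trp1"),
        "tyr": ({"pep[c]": -2, "e4p[c]": -1, "glu[c]": -1, "nadph[c]": -1,
                 "tyr[c]": 1, "akg[c]": 1, "co2[c]": 1, "nadp[c]": 1,
                 "pi[c]": 3}, "g_tyr1"),
        "val": ({"pyr[c]": -2, "glu[c]": -1, "nadph[c]": -1,
                 "val[c]": 1, "akg[c]": 1, "co2[c]": 1, "nadp[c]": 1},
                "g_val1"),
    }
    for aa, (stoich, gene) in syn.items():
        b.rxn(f"SYN_{aa}", stoich, 0, 1000, subsystem=AA, gpr=gene)
    b.rxn("GCS", {"gly[c]": -2, "nad[c]": -1,
                  "ser[c]": 1, "co2[c]": 1, "nh3[c]": 1, "nadh[c]": 1},
          0, 1000, subsystem=AA, gpr="g_gcv")
    b.rxn("SER_DEAM", {"ser[c]": -1, "pyr[c]": 1, "nh3[c]": 1},
          0, 1000, subsystem=AA, gpr="g_sda")
    b.rxn("DEG_ile", {"ile[c]": -1, "akg[c]": -1, "coa[c]": -2, "nad[c]": -3,
                      "glu[c]": 1, "accoa[c]": 2, "co2[c]": 2, "nadh[c]": 3},
          0, 1000, subsystem=AA, gpr="g_ild")
    b.rxn("DEG_leu", {"leu[c]": -1, "akg[c]": -1, "coa[c]": -3, "atp[c]": -1,
                      "nad[c]": -2, "glu[c]": 1, "accoa[c]": 3, "adp[c]": 1,
                      "pi[c]": 1, "nadh[c]": 2},
          0, 1000, subsystem=AA, gpr="g_lud")
    b.rxn("DEG_lys", {"lys[c]": -1, "akg[c]": -2, "coa[c]": -2, "nad[c]": -4,
                      "glu[c]": 2, "accoa[c]": 2, "co2[c]": 2, "nadh[c]": 4},
          0, 1000, subsystem=AA, gpr="g_lyd")

    # ----- nucleotides, cofactor pools, cell wall ------------------------
    NT = "Nucleotide metabolism"
    b.rxn("SYN_ntp", {"ru5p[c]": -1, "nh3[c]": -4, "co2[c]": -2,
                      "atp[c]": -4, "ntp[c]": 1, "adp[c]": 4, "pi[c]": 4},
          0, 1000, subsystem=NT, gpr="g_prs", balance=False)
    b.rxn("SYN_dntp", {"ntp[c]": -1, "nadph[c]": -1,
                       "dntp[c]": 1, "nadp[c]": 1},
          0, 1000, subsystem=NT, gpr="g_rnr", balance=False)
    # de novo synthesis lumps for the currency pools, so every cofactor has
    # a net production route (the adenine/nicotinamide/CoA moieties are not
    # conserved dead pools)
    b.rxn("SYN_amp", {"ru5p[c]": -1, "gly[c]": -1, "co2[c]": -3,
                      "nh3[c]": -4, "atp[c]": -4,
                      "amp[c]": 1, "adp[c]": 4, "pi[c]": 4},
          0, 1000, subsystem=NT, gpr="g_ade")
    b.rxn("SYN_nad", {"amp[c]": -1, "ru5p[c]": -1, "asp[c]": -1,
                      "dhap[c]": -1, "atp[c]": -2, "nh3[c]": -1,
                      "nad[c]": 1, "adp[c]": 2, "pi[c]": 3, "co2[c]": 1},
          0, 1000, subsystem="Cofactors and vitamins", gpr="g_nds")
    b.rxn("SYN_nadp", {"nad[c]": -1, "atp[c]": -1,
                       "nadp[c]": 1, "adp[c]": 1},
          0, 1000, subsystem="Cofactors and vitamins", gpr="g_ndk")
    b.rxn("SYN_coa", {"amp[c]": -1, "pyr[c]": -2, "asp[c]": -1,
                      "cys[c]": -1, "atp[c]": -4, "nadph[c]": -2,
                      "coa[c]": 1, "adp[c]": 4, "pi[c]": 2, "co2[c]": 2,
                      "nadp[c]": 2},
          0, 1000, subsystem="Cofactors and vitamins", gpr="g_cab")
    b.rxn("SYN_glucan", {"g6p[c]": -1, "atp[c]": -1,
                         "glucan[c]": 1, "adp[c]": 1, "pi[c]": 2},
          0, 1000, subsystem=CH, gpr="g_ugp")

    # ----- fatty acid synthesis and the PUFA chain -----------------------
    LP = "Lipid metabolism"
    ox = spec.oxygen_per_desaturation
    ne = spec.nadph_per_elongation
    b.rxn("ACC", {"accoa[c]": -1, "co2[c]": -1, "atp[c]": -1,
                  "malcoa[c]": 1, "adp[c]": 1, "pi[c]": 1},
          0, 1000, subsystem=LP, gpr="g_acc")
    b.rxn("FAS", {"accoa[c]": -1, "malcoa[c]": -7, "nadph[c]": -14,
                  "c160[c]": 1, "co2[c]": 7, "coa[c]": 8, "nadp[c]": 14},
          0, 1000, subsystem=LP, gpr="g_fas")
    b.rxn("FAA", {"c160[c]": -1, "coa[c]": -1, "atp[c]": -1,
                  "c160coa[c]": 1, "amp[c]": 1, "ppi[c]": 1},
          0, 1000, subsystem=LP, gpr="g_faa")

    def elongase(rxn_id, sub, prod, gene):
        b.rxn(rxn_id,
              {f"{sub}[c]": -1, "malcoa[c]": -1, "nadph[c]": -ne,
               f"{prod}[c]": 1, "co2[c]": 1, "coa[c]": 1, "nadp[c]": ne},
              0, 1000, subsystem=LP, gpr=gene)

    def desaturase(rxn_id, sub, prod, gene):
        b.rxn(rxn_id,
              {f"{sub}[c]": -1, "o2[c]": -ox, "nadh[c]": -1,
               f"{prod}[c]": 1, "nad[c]": 1},
              0, 1000, subsystem=LP, gpr=gene)

    elongase("ELO1", "c160coa", "c180coa", "g_elo1")
    desaturase("D9", "c180coa", "c181coa", "g_d9a, g_d9b, g_d9c")
    desaturase("D12", "c181coa", "c182coa", "g_d12")
    desaturase("D6", "c182coa", "c183n6coa", "g_d6a, g_d6b")
    elongase("GLELO", "c183n6coa", "c203n6coa", "g_glelo, g_maelo, g_malce1")
    if spec.delta5_present:
        desaturase("D5", "c203n6coa", "c204n6coa", "g_d5")
        b.rxn("HYD_ARA", {"c204n6coa[c]": -1, "ara[c]": 1, "coa[c]": 1},
              0, 1000, subsystem=LP, gpr="g_hyd1, g_hyd2")
    if spec.include_omega3:
        desaturase("D15", "c182coa", "c183n3coa", "g_d15")
        desaturase("D6w3", "c183n3coa", "c184n3coa", "g_d6a, g_d6b")
        elongase("ELOw3", "c184n3coa", "c204n3coa",
                 "g_glelo, g_maelo, g_malce1")
        desaturase("D5w3", "c204n3coa", "c205n3coa", "g_d5")
        b.rxn("HYD_EPA", {"c205n3coa[c]": -1, "epa[c]": 1, "coa[c]": 1},
              0, 1000, subsystem=LP, gpr="g_hyd1, g_hyd2")

    # ----- biomass and maintenance ---------------------------------------
    composition, masses = default_biomass_composition(spec.gam, spec.ngam)
    biomass = build_biomass_reaction(
        composition, masses, reaction_id="BIOMASS", biomass_metabolite=None
    )
    biomass.subsystem = "Biomass"
    b.model.add_reaction(biomass)
    model = add_ngam(b.model, spec.ngam, maintenance_id="ATPM")
    model.objective_id = "BIOMASS"
    model.validate()

    nadph_reactions = sorted(
        r.id for r in model.reactions if "nadph[c]" in r.stoichiometry
    )
    nadph_producers = [
        r
        for r in ("PPP1", "PPP2", "ME")
        if model.has_reaction(r)
    ]
    # audited by construction: single-route genes for biomass precursors on
    # MG (all amino-acid synthesis lumps, nucleotide/cofactor/cell-wall/lipid
    # synthesis, glycolysis entry, nitrate assimilation chain, the oxidative
    # PPP as the sole ribulose-5-P source, and the mitochondrial PDH/citrate
    # route to 2-oxoglutarate). Genes with bypasses (e.g. pyruvate kinase via
    # serine deamination, ATP-citrate lyase via the ile synthesis/degradation
    # loop) are deliberately absent.
    expected_mg_essential = sorted(
        {
            "g_hxk", "g_gly1", "g_tpi", "g_gpp", "g_zwf", "g_gnd", "g_tkt",
            "g_idh", "g_cs", "g_pdh1", "g_pdh2", "g_pdh3",
            "g_nr", "g_nir", "g_sua", "g_ast", "g_gly2",
            "g_prs", "g_rnr", "g_ade", "g_adk", "g_ugp", "g_acc", "g_fas",
        }
        | {gene for _, (_, gene) in syn.items()}
    )
    truth = GroundTruth(
        biomass_reaction="BIOMASS",
        maintenance_reaction="ATPM",
        ara_exchange="EX_ara",
        epa_exchange="EX_epa" if spec.include_omega3 else None,
        glucose_exchange="EX_glc",
        oxygen_exchange="EX_o2",
        nitrate_exchange="EX_no3",
        me_reaction="ME" if spec.me_present else None,
        me_gene="g_me" if spec.me_present else None,
        ppp_reactions=["PPP1", "PPP2"] if spec.ppp_present else [],
        nadph_reactions=nadph_reactions,
        nadph_producers=nadph_producers,
        nitrate_reductase_gene="g_nr",
        nitrite_reductase_gene="g_nir",
        amino_acid_synthesis_genes={aa: gene for aa, (_, gene) in syn.items()},
        amino_acid_exchanges={aa: f"EX_{aa}" for aa in AA_TABLE},
        expected_mg_essential_genes=expected_mg_essential,
        rhamnose_lyase_reaction="RHA_LYASE",
        orphan_sugar_exchange="EX_orph" if spec.include_orphan_sugar else None,
        # bracket of the ARA-vs-oxygen optimum under the production scenario
        # (MG at the spec glucose uptake, growth pinned >= 0.03); follows from
        # the O2 budget of desaturation + respiration at full glucose use and
        # is verified numerically by the robustness tests.
        oxygen_optimum_window=(0.5, 3.0),
    )
    return model, truth


def mini_alpina_media(spec: Optional[MiniAlpinaSpec] = None):
    """The MG / YE medium presets matching mini-alpina's exchange ids."""
    spec = spec or MiniAlpinaSpec()
    always_open = frozenset(
        {"EX_o2", "EX_co2", "EX_h2o", "EX_h", "EX_pi", "EX_so4"}
    )
    mg = Medium(
        name="MG",
        overrides={
            "EX_glc": (-spec.glucose_uptake, 1000.0),
            "EX_no3": (-1000.0, 1000.0),
        },
        always_open=always_open,
    )
    ye_overrides = dict(mg.overrides)
    for aa in AA_TABLE:
        ye_overrides[f"EX_{aa}"] = (-spec.amino_acid_uptake, 1000.0)
    ye = Medium(name="YE", overrides=ye_overrides, always_open=always_open)
    return mg, ye


# ---------------------------------------------------------------------------
# Random viable models
# ---------------------------------------------------------------------------


@dataclass
class RandomModelSpec:
    n_metabolites: int = 12
    n_reactions: int = 12
    n_genes: int = 6
    reversibility_fraction: float = 0.2
    seed: int = 0
    # decoration arity; 1/1 gives unimolecular networks, for which LP gap
    # detection provably coincides with graph reachability
    max_substrates: int = 2
    max_products: int = 2
    # orient every decoration from lower- to higher-indexed metabolites so
    # the decoration graph is a DAG (no internal loops can carry flux)
    acyclic: bool = False

    BACKBONE_REACTIONS = 4  # exchange, transport, conversion, biomass

    def validate(self):
        if self.n_reactions < self.BACKBONE_REACTIONS:
            raise SpecError(
                f"need at least {self.BACKBONE_REACTIONS} reactions for the "
                "uptake->biomass backbone"
            )
        if self.n_metabolites < 3:
            raise SpecError("need at least 3 metabolites")


def generate_random_viable_model(
    spec: Optional[RandomModelSpec] = None,
) -> MetabolicModel:
    """Seed-deterministic random model with a guaranteed-viable backbone.

    The backbone ``EX_n0 -> n0[e] -> n0[c] -> p0[c] -> biomass`` always
    carries flux, so FBA growth is positive; decorating reactions connect
    randomly chosen metabolites (possibly fresh dead-end ones), which can
    create gaps on purpose.
    """
    spec = spec or RandomModelSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = MetabolicModel(id=f"random_{spec.seed}")
    model.add_metabolite(Metabolite("n0[e]", "nutrient", "e"))
    model.add_metabolite(Metabolite("n0[c]", "nutrient", "c"))
    model.add_metabolite(Metabolite("p0[c]", "precursor", "c"))
    extra = max(0, spec.n_metabolites - 3)
    for k in range(extra):
        model.add_metabolite(Metabolite(f"x{k}[c]", f"decoration {k}", "c"))
    model.add_reaction(
        Reaction("EX_n0", "nutrient exchange", {"n0[e]": -1.0},
                 -10.0, 1000.0, rtype="exchange", subsystem="Exchange")
    )
    model.add_reaction(
        Reaction("T_n0", "nutrient transport", {"n0[e]": -1.0, "n0[c]": 1.0},
                 0.0, 1000.0, rtype="transport", subsystem="Transport")
    )
    model.add_reaction(
        Reaction("CONV", "conversion", {"n0[c]": -1.0, "p0[c]": 1.0},
                 0.0, 1000.0, subsystem="Backbone",
                 gpr=GprRule("g0" if spec.n_genes > 0 else ""))
    )
    model.add_reaction(
        Reaction("BIOMASS", "biomass", {"p0[c]": -1.0},
                 0.0, 1000.0, subsystem="Biomass")
    )
    model.objective_id = "BIOMASS"
    genes = [f"g{k}" for k in range(spec.n_genes)]
    cyt_mets = [m.id for m in model.metabolites if m.compartment == "c"]
    for k in range(spec.n_reactions - spec.BACKBONE_REACTIONS):
        n_sub = int(rng.integers(1, spec.max_substrates + 1))
        n_prod = int(rng.integers(1, spec.max_products + 1))
        chosen = rng.choice(len(cyt_mets), size=n_sub + n_prod, replace=False)
        if spec.acyclic:
            chosen = np.sort(chosen)
        stoich = {}
        for idx in chosen[:n_sub]:
            stoich[cyt_mets[idx]] = stoich.get(cyt_mets[idx], 0.0) - 1.0
        for idx in chosen[n_sub:]:
            stoich[cyt_mets[idx]] = stoich.get(cyt_mets[idx], 0.0) + 1.0
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            continue
        reversible = rng.random() < spec.reversibility_fraction
        gene = genes[int(rng.integers(0, len(genes)))] if genes else ""
        model.add_reaction(
            Reaction(
                f"RND{k}",
                f"decoration {k}",
                stoich,
                -1000.0 if reversible else 0.0,
                1000.0,
                subsystem="Decoration",
                gpr=GprRule(gene),
            )
        )
    model.validate()
    return model


def perturb_remove_reactions(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Copy of the model with the listed reactions removed (never biomass)."""
    new = model.copy()
    for rxn_id in reaction_ids:
        if rxn_id == new.objective_id:
            raise SpecError("refusing to remove the biomass/objective reaction")
        new.remove_reaction(rxn_id)
    new.validate()
    return new
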