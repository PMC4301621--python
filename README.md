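# oleaflux

Constraint-based metabolic modelling toolkit for oleaginous-fungus PUFA
networks. It provides, as a tested reusable package, the full analysis
pipeline used for genome-scale models of arachidonic-acid producers:

* **Model core** — compartmentalized metabolites/reactions, flux bounds,
  boolean gene–protein–reaction (GPR) rules (AND/OR/parentheses; comma
  lists parse as isozyme ORs), stoichiometric-matrix construction,
  elemental/charge auditing (`oleaflux.core`).
* **I/O** — SBML Level 3 + FBC v2 (via python-libsbml) and a plain-text
  TSV bundle (`reactions.tsv`, `metabolites.tsv`, `genes.tsv`) with exact
  equation round-trips; result tables as TSV (`oleaflux.io`).
* **FBA engine** — FBA, FVA, robustness scans, medium application with
  shipped MG/YE presets, sole-source utilization screens, all on the
  deterministic HiGHS solver (`oleaflux.fba`).
* **MOMA** — quadratic minimization of metabolic adjustment for gene or
  reaction knockouts, plus a labelled L1 variant and changed-reaction
  counting (`oleaflux.moma`).
* **Essentiality screens** — single-gene / single-reaction deletion under
  a medium, medium-to-medium comparison with per-subsystem tallies
  (`oleaflux.essentiality`).
* **Gap detection** — blocked (no-production / no-consumption) metabolites
  and dead-end reactions via an LP relaxation of the classical MILP
  (`oleaflux.gaps`).
* **Biomass builder** — six-component macromolecular biomass equation
  (protein, DNA, RNA, lipid, cell wall, small-molecule pool) with GAM/NGAM
  handling (`oleaflux.biomass`).
* **Cofactor accounting** — metabolite-centric differential flux reports
  across conditions and producer/consumer share decomposition
  (`oleaflux.cofactors`).
* **Synthetic models** — a deterministic curated test model
  ("mini-alpina", ~180 reactions, 4 compartments) embodying the
  glucose→acetyl-CoA→malonyl-CoA→palmitate→ARA/EPA
  elongation/desaturation chain, malic enzyme and oxidative PPP as NADPH
  sources, nitrate assimilation and 20 amino-acid exchanges, with a
  machine-readable ground-truth record; plus seeded random viable models
  for property testing (`oleaflux.synthetic`).

No external data files are required: every model used by the test suite is
generated programmatically.

## CLI

The `oleaflux` command orchestrates the scenarios. Uptake rates are given
as positive magnitudes; every run writes a `manifest.json` plus TSV/JSON
results into `--out`. Exit codes: 0 optimal, 3 infeasible, 2 usage error.

```bash
# generate the bundled synthetic model (TSV bundle + SBML + ground truth)
oleaflux make-model --out demo

# growth on minimal medium at a glucose uptake of 0.8 mmol/gDW/h
oleaflux fba demo/model --medium mg --glucose-uptake 0.8 --out demo/growth

# production scenario: growth pinned, ARA exchange as objective,
# malic-enzyme knockout under MOMA
oleaflux moma demo/model --medium mg --growth 0.03 --objective EX_ara \
    --genes g_me --out demo/moma

# oxygen robustness scan for ARA production
oleaflux robustness demo/model --medium mg --exchange EX_o2 \
    --objective EX_ara --start 0 --stop 20 --step 0.5 --min-growth 0.03 \
    --out demo/o2

# gene essentiality on MG vs YE media
oleaflux essentiality demo/model --medium mg --compare-medium ye --out demo/ess

# sole carbon-source screen
oleaflux sources demo/model --medium mg --replace EX_glc \
    --candidates EX_glyc,EX_etoh,EX_rha,EX_orph --out demo/src

# NADPH differential flux report between two production levels
oleaflux cofactor-report demo/model --medium mg --metabolite "nadph[c]" \
    --conditions EX_ara:0.06,EX_ara:0.03 --out demo/nadph

# blocked metabolites / dead-end reactions
oleaflux gaps demo/model --out demo/gaps

# consolidated five-section report
oleaflux report demo/model --out demo/report
```

Media can be the shipped presets (`mg`, `ye`) or a JSON file with
`overrides` (exchange id → `[lower, upper]`) and an `always_open` list.

## Conventions

* Fluxes in mmol·gDW⁻¹·h⁻¹; biomass flux in h⁻¹.
* Exchanges are written `met[e] <=> ∅`; negative flux is uptake.
* Default bounds: irreversible [0, 1000], reversible [−1000, 1000].
* Compartment tags as id suffixes: `[e]` extracellular, `[c]` cytosol,
  `[m]` mitochondrion, `[x]` peroxisome.
* LP/QP results are deterministic across runs; at degenerate optima only
  the objective value is contract-stable, the flux vector is "an optimal
  vertex".
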