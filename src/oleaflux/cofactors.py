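"""Metabolite-centric flux bookkeeping across conditions.

Differential flux reports list every reaction touching a chosen metabolite
with its flux under two conditions and flag those whose absolute change
exceeds a threshold (default 1e-6 mmol gDW^-1 h^-1, strict comparison).
Producer/consumer splits decompose a metabolite's steady-state turnover
into percentage shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import MetabolicModel, reactions_involving
from .fba import FluxDistribution

DEFAULT_CHANGE_THRESHOLD = 1e-6


def _base_id(met_id: str) -> str:
    """Strip a trailing [compartment] tag."""
    if met_id.endswith("]") and "[" in met_id:
        return met_id[: met_id.rindex("[")]
    return met_id


@dataclass
class DifferentialFluxReport:
    metabolite_id: str
    condition_a: str
    condition_b: str
    threshold: float
    rows: dict  # reaction id -> (flux_a, flux_b, abs_change)

    @property
    def changed(self) -> set:
        return {r for r, (_, _, d) in self.rows.items() if d > self.threshold}

    @property
    def n_changed(self) -> int:
        return len(self.changed)


@dataclass
class ProducerConsumerSplit:
    metabolite_id: str
    turnover: dict  # reaction id -> signed turnover (coefficient x flux)
    production_total: float
    consumption_total: float
    producer_shares: dict  # reaction id -> percent of production
    consumer_shares: dict  # reaction id -> percent of consumption

    @property
    def empty(self) -> bool:
        return self.production_total == 0 and self.consumption_total == 0


def differential_flux_report(
    model: MetabolicModel,
    metabolite_id: str,
    solution_a: FluxDistribution,
    solution_b: FluxDistribution,
    threshold: float = DEFAULT_CHANGE_THRESHOLD,
    condition_a: str = "A",
    condition_b: str = "B",
    pooled: bool = False,
) -> DifferentialFluxReport:
    """Flux pairs across two conditions for reactions touching a metabolite.

    By default the report is compartment-specific (the metabolite id carries
    its compartment tag); with ``pooled=True`` all compartments sharing the
    metabolite's base id are merged into one report.
    """
    if set(solution_a.fluxes) != set(solution_b.fluxes):
        raise ValueError("solutions cover different reaction universes")
    if pooled:
        base = _base_id(metabolite_id)
        met_ids = [m.id for m in model.metabolites if _base_id(m.id) == base]
        if not met_ids:
            raise KeyError(f"no metabolite with base id {base!r}")
    else:
        met_ids = [model.metabolite(metabolite_id).id]
    rxn_ids = set()
    for met_id in met_ids:
        rxn_ids |= reactions_involving(model, met_id)
    rows = {}
    for rid in sorted(rxn_ids):
        fa = solution_a.fluxes[rid]
        fb = solution_b.fluxes[rid]
        rows[rid] = (fa, fb, abs(fa - fb))
    return DifferentialFluxReport(
        metabolite_id=metabolite_id,
        condition_a=condition_a,
        condition_b=condition_b,
        threshold=threshold,
        rows=rows,
    )


def producer_consumer_split(
    model: MetabolicModel,
    metabolite_id: str,
    solution: FluxDistribution,
) -> ProducerConsumerSplit:
    """Decompose a metabolite's turnover into producer/consumer percent shares.

    Turnover of reaction r is (stoichiometric coefficient) x (flux);
    positive turnover is production. Reversible reactions are classified by
    the realized sign of their turnover. At steady state production and
    consumption totals agree; an all-zero turnover yields a defined empty
    split rather than a division error.
    """
    met = model.metabolite(metabolite_id)
    turnover = {}
    for rid in sorted(reactions_involving(model, met.id)):
        coef = model.reaction(rid).stoichiometry[met.id]
        turnover[rid] = coef * solution.fluxes[rid]
    production = sum(t for t in turnover.values() if t > 0)
    consumption = -sum(t for t in turnover.values() if t < 0)
    producer_shares = (
        {r: 100.0 * t / production for r, t in turnover.items() if t > 0}
        if production > 0
        else {}
    )
    consumer_shares = (
        {r: 100.0 * (-t) / consumption for r, t in turnover.items() if t < 0}
        if consumption > 0
        else {}
    )
    return ProducerConsumerSplit(
        metabolite_id=met.id,
        turnover=turnover,
        production_total=production,
        consumption_total=consumption,
        producer_shares=producer_shares,
        consumer_shares=consumer_shares,
    )


def flux_ratio_change(flux_before: float, flux_after: float) -> float:
    """Percent change 100 x (after - before) / before.

    Undefined for a zero baseline; raises ValueError so callers can report
    "undefined" rather than a spurious number. Rounding is left to the
    presentation layer.
    """
    if flux_before == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    return 100.0 * (flux_after - flux_before) / flux_before


def percent_of(part: float, whole: float) -> float:
    """Plain percentage 100 x part / whole (whole must be nonzero)."""
    if whole == 0:
        raise ValueError("percentage is undefined for a zero denominator")
    return 100.0 * part / whole
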