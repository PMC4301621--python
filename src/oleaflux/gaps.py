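"""Detection of blocked (gap) metabolites and dead-end reactions.

A metabolite is a *no-production* gap when no flux vector within bounds can
give it strictly positive net production while every other metabolite is
allowed to accumulate (relaxed mass balance S·v >= 0). This LP relaxation
with a small production demand epsilon replaces the classical MILP
formulation; the two agree on which metabolites can ever be produced.
*Root* gaps additionally lack any producing reaction structurally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import MetabolicModel, build_stoichiometric_matrix
from .fba import Medium, apply_medium

DEMAND_EPS = 1e-4


@dataclass
class GapReport:
    no_production: set
    no_consumption: set
    root_no_production: set
    root_no_consumption: set
    dead_end_reactions: set

    @property
    def blocked_metabolites(self) -> set:
        return self.no_production | self.no_consumption


def _structural_producers(model: MetabolicModel):
    """met id -> True if some reaction can produce it given reversibility."""
    producible, consumable = set(), set()
    for rxn in model.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            if coef > 0:
                if rxn.upper_bound > 0:
                    producible.add(met_id)
                if rxn.lower_bound < 0:
                    consumable.add(met_id)
            elif coef < 0:
                if rxn.upper_bound > 0:
                    consumable.add(met_id)
                if rxn.lower_bound < 0:
                    producible.add(met_id)
    return producible, consumable


def _net_flux_feasible(S, lo, hi, row: int, sense: str, eps: float) -> bool:
    """Feasibility of S·v >= 0 (componentwise) with (S·v)_row >= eps
    (sense='produce') or (S·v)_row <= -eps with other rows >= 0
    (sense='consume')."""
    m, _ = S.shape
    # -S v <= 0 for all rows except `row`; the demand row is flipped per sense
    A = -S.tocsr(copy=True).toarray() if sparse.issparse(S) else -S.copy()
    b = np.zeros(m)
    if sense == "produce":
        b[row] = -eps  # -(S v)_row <= -eps  <=>  (S v)_row >= eps
    else:
        A[row, :] = -A[row, :]  # (S v)_row <= -eps
        b[row] = -eps
    res = linprog(
        np.zeros(S.shape[1]),
        A_ub=A,
        b_ub=b,
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    return res.status == 0


def find_blocked_metabolites(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    eps: float = DEMAND_EPS,
) -> GapReport:
    """Classify every metabolite as producible/consumable under the medium."""
    conditioned = apply_medium(model, medium) if medium is not None else model
    S = build_stoichiometric_matrix(conditioned)
    lo = np.array([r.lower_bound for r in conditioned.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in conditioned.reactions], dtype=float)
    producible_structural, consumable_structural = _structural_producers(conditioned)

    no_production, no_consumption = set(), set()
    root_no_production, root_no_consumption = set(), set()
    for i, met in enumerate(conditioned.metabolites):
        if met.id not in producible_structural:
            no_production.add(met.id)
            root_no_production.add(met.id)
        elif not _net_flux_feasible(S, lo, hi, i, "produce", eps):
            no_production.add(met.id)
        if met.id not in consumable_structural:
            no_consumption.add(met.id)
            root_no_consumption.add(met.id)
        elif not _net_flux_feasible(S, lo, hi, i, "consume", eps):
            no_consumption.add(met.id)

    blocked = no_production | no_consumption
    dead_end = set()
    for rxn in conditioned.reactions:
        if rxn.lower_bound == 0 and rxn.upper_bound == 0:
            dead_end.add(rxn.id)
        elif any(met_id in blocked for met_id in rxn.stoichiometry):
            # a reaction touching a no-production metabolite it consumes, or
            # a no-consumption metabolite it produces, can never carry flux
            if _touches_blocking(rxn, no_production, no_consumption):
                dead_end.add(rxn.id)
    return GapReport(
        no_production=no_production,
        no_consumption=no_consumption,
        root_no_production=root_no_production,
        root_no_consumption=root_no_consumption,
        dead_end_reactions=dead_end,
    )


def _touches_blocking(rxn, no_production, no_consumption) -> bool:
    forward_ok = rxn.upper_bound > 0
    reverse_ok = rxn.lower_bound < 0
    for met_id, coef in rxn.stoichiometry.items():
        consumed_fwd = coef < 0
        if consumed_fwd and met_id in no_production:
            forward_ok = False
        if not consumed_fwd and met_id in no_consumption:
            forward_ok = False
        if consumed_fwd and met_id in no_consumption:
            reverse_ok = False
        if not consumed_fwd and met_id in no_production:
            reverse_ok = False
    return not forward_ok and not reverse_ok


def find_blocked_reactions(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    eps: float = DEMAND_EPS,
) -> set:
    """Reaction ids that can never carry flux.

    A reaction is blocked when neither direction admits a flux of magnitude
    >= eps under the relaxed balance S·v >= 0 (accumulation allowed). On
    networks without accumulation artifacts this coincides with FVA ranges
    of [0, 0]; the relaxation keeps it consistent with the metabolite gap
    semantics above and with graph reachability on acyclic networks.
    """
    conditioned = apply_medium(model, medium) if medium is not None else model
    S = build_stoichiometric_matrix(conditioned)
    lo = np.array([r.lower_bound for r in conditioned.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in conditioned.reactions], dtype=float)
    m, n = S.shape
    blocked = set()
    for j, rxn in enumerate(conditioned.reactions):
        can_forward = False
        can_reverse = False
        if hi[j] >= eps:
            lo2 = lo.copy()
            lo2[j] = max(lo2[j], eps)
            can_forward = _relaxed_feasible(S, lo2, hi)
        if lo[j] <= -eps:
            hi2 = hi.copy()
            hi2[j] = min(hi2[j], -eps)
            can_reverse = _relaxed_feasible(S, lo, hi2)
        if not can_forward and not can_reverse:
            blocked.add(rxn.id)
    return blocked


def _relaxed_feasible(S, lo, hi) -> bool:
    res = linprog(
        np.zeros(S.shape[1]),
        A_ub=-S,
        b_ub=np.zeros(S.shape[0]),
        bounds=np.column_stack([lo, hi]),
        method="highs",
    )
    return res.status == 0
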