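"""Minimization of metabolic adjustment (MOMA).

Given a wild-type reference flux vector, the knockout flux state is the
Euclidean projection of the reference onto the knockout model's feasible
set {v : S·v = 0, l <= v <= u} — a strictly convex quadratic program with a
unique minimizer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, minimize
from scipy import sparse

from .core import MetabolicModel, build_stoichiometric_matrix
from .fba import FluxDistribution


@dataclass
class MomaSolution:
    fluxes: dict
    distance: Optional[float]
    status: str

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


def knockout_gene(model: MetabolicModel, gene_ids: Iterable[str]) -> MetabolicModel:
    """Copy of the model with GPR-inactivated reactions blocked to (0, 0)."""
    gene_ids = set(gene_ids)
    unknown = gene_ids - set(model.genes)
    if unknown:
        raise KeyError(f"unknown gene(s): {sorted(unknown)}")
    new = model.copy()
    for rxn in new.reactions:
        if rxn.gpr.is_empty:
            continue
        if not rxn.gpr.evaluate(gene_ids):
            rxn.lower_bound = 0.0
            rxn.upper_bound = 0.0
    return new


def knockout_reactions(
    model: MetabolicModel, reaction_ids: Iterable[str]
) -> MetabolicModel:
    """Copy of the model with the listed reactions blocked to (0, 0)."""
    new = model.copy()
    for rxn_id in reaction_ids:
        rxn = new.reaction(rxn_id)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return new


def solve_moma(
    model: MetabolicModel,
    reference: FluxDistribution,
    knockout_genes: Iterable[str] = (),
    knockout_reaction_ids: Iterable[str] = (),
    tol: float = 1e-10,
) -> MomaSolution:
    """Minimize sum_j (v_j - v_ref,j)^2 over the knockout model's feasible set.

    The reference must cover every reaction of the model. The solver is
    scipy's trust-region constrained QP; the result is checked for primal
    feasibility (|S·v| and bound violations <= 1e-6) before being reported
    optimal.
    """
    ko = model
    if knockout_genes:
        ko = knockout_gene(ko, knockout_genes)
    if knockout_reaction_ids:
        ko = knockout_reactions(ko, knockout_reaction_ids)

    rxn_ids = [r.id for r in ko.reactions]
    missing = [rid for rid in rxn_ids if rid not in reference.fluxes]
    if missing:
        raise ValueError(f"reference lacks fluxes for {missing[:5]} ...")
    w = np.array([reference.fluxes[rid] for rid in rxn_ids], dtype=float)
    lo = np.array([r.lower_bound for r in ko.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in ko.reactions], dtype=float)
    S = build_stoichiometric_matrix(ko)

    # quick infeasibility check via an LP-free shortcut: bounds crossing
    if np.any(lo > hi + 1e-12):
        return MomaSolution({}, None, "infeasible")

    # if the clipped reference already satisfies S·v = 0 it is the optimum
    v0 = np.clip(w, lo, hi)
    if np.max(np.abs(S @ v0)) <= 1e-12 and np.allclose(v0, w):
        return MomaSolution(dict(zip(rxn_ids, v0.tolist())), 0.0, "optimal")

    n = len(rxn_ids)
    identity = sparse.identity(n, format="csr")

    res = minimize(
        lambda v: 0.5 * float(np.dot(v - w, v - w)),
        v0,
        jac=lambda v: v - w,
        hess=lambda v: identity,
        bounds=Bounds(lo, hi),
        constraints=[LinearConstraint(S, 0.0, 0.0)],
        method="trust-constr",
        options={"gtol": tol, "xtol": 1e-14, "maxiter": 2000, "verbose": 0},
    )
    v = np.asarray(res.x, dtype=float)
    feasible = (
        np.max(np.abs(S @ v)) <= 1e-6
        and np.all(v >= lo - 1e-6)
        and np.all(v <= hi + 1e-6)
    )
    if not feasible:
        # distinguish "knockout model infeasible" from solver failure via FBA
        from .fba import solve_fba

        probe = solve_fba(ko, rxn_ids[0], direction="min")
        status = "infeasible" if probe.status == "infeasible" else "error"
        return MomaSolution({}, None, status)
    v = np.clip(v, lo, hi)
    distance = math.sqrt(float(np.dot(v - w, v - w)))
    return MomaSolution(dict(zip(rxn_ids, v.tolist())), distance, "optimal")


def solve_moma_l1(
    model: MetabolicModel,
    reference: FluxDistribution,
    knockout_genes: Iterable[str] = (),
) -> MomaSolution:
    """Linear (L1) adjustment-minimization variant — an explicit alternative
    to quadratic MOMA, never silently substituted for it.

    Minimizes sum_j |v_j - v_ref,j| via the standard split into positive and
    negative deviation variables. The reported ``distance`` is still the
    Euclidean norm of the adjustment so the two variants are comparable.
    """
    from scipy.optimize import linprog

    ko = knockout_gene(model, knockout_genes) if knockout_genes else model
    rxn_ids = [r.id for r in ko.reactions]
    w = np.array([reference.fluxes[rid] for rid in rxn_ids], dtype=float)
    lo = np.array([r.lower_bound for r in ko.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in ko.reactions], dtype=float)
    S = build_stoichiometric_matrix(ko, sparse_format=True)
    n = len(rxn_ids)
    # variables: [v, d+, d-]; v - d+ + d- = w; S v = 0
    A_eq = sparse.bmat(
        [
            [S, None, None],
            [sparse.identity(n), -sparse.identity(n), sparse.identity(n)],
        ],
        format="csr",
    )
    b_eq = np.concatenate([np.zeros(S.shape[0]), w])
    c = np.concatenate([np.zeros(n), np.ones(n), np.ones(n)])
    bounds = (
        [(l, h) for l, h in zip(lo, hi)]
        + [(0, None)] * n
        + [(0, None)] * n
    )
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if res.status != 0:
        return MomaSolution({}, None, "infeasible" if res.status == 2 else "error")
    v = res.x[:n]
    distance = math.sqrt(float(np.dot(v - w, v - w)))
    return MomaSolution(dict(zip(rxn_ids, v.tolist())), distance, "optimal")


def count_changed_reactions(
    reference: FluxDistribution,
    solution,
    threshold: float = 1e-6,
):
    """Number and ids of reactions with |v - v_ref| strictly above threshold."""
    ref_ids = set(reference.fluxes)
    sol_ids = set(solution.fluxes)
    if ref_ids != sol_ids:
        raise ValueError(
            "flux vectors cover different reaction universes "
            f"(only-reference: {sorted(ref_ids - sol_ids)[:3]}, "
            f"only-solution: {sorted(sol_ids - ref_ids)[:3]})"
        )
    changed = sorted(
        rid
        for rid in ref_ids
        if abs(solution.fluxes[rid] - reference.fluxes[rid]) > threshold
    )
    return len(changed), changed
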