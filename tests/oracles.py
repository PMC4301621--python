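"""Independent oracles used by the test suite.

These deliberately avoid the solver paths they check: LP results are
compared against exhaustive basic-feasible-solution enumeration, MOMA
against Dykstra's alternating-projection method, gap detection against a
graph reachability closure, and GPR evaluation against a brute-force
truth-table built by Python's own boolean evaluator.
"""

from __future__ import annotations

import itertools
import re

import numpy as np
import scipy.linalg

from oleaflux.core import build_stoichiometric_matrix


# ---------------------------------------------------------------------------
# LP vertex enumeration
# ---------------------------------------------------------------------------


def enumerate_vertices(S, lb, ub, tol=1e-9):
    """All basic feasible solutions of {S v = 0, lb <= v <= ub}.

    Every subset of n - rank(S) variables is pinned to one of its bounds and
    the rest solved from the balance equations; infeasible or inconsistent
    combinations are discarded. Any bounded LP optimum over the polytope is
    attained at one of these points.
    """
    S = np.asarray(S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    vertices = []
    for fixed in itertools.combinations(range(n), k):
        free = [j for j in range(n) if j not in fixed]
        for bits in itertools.product((0, 1), repeat=k):
            v = np.zeros(n)
            for j, bit in zip(fixed, bits):
                v[j] = ub[j] if bit else lb[j]
            if free:
                A = S[:, free]
                b = -S[:, list(fixed)] @ v[list(fixed)] if fixed else np.zeros(m)
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = sol
            if S.size and np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            vertices.append(v)
    return vertices


def lp_oracle_max(S, lb, ub, c):
    """Optimal value of max c.v over the flux polytope by enumeration."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    return max(float(np.dot(c, v)) for v in vertices)


def fva_oracle(S, lb, ub, obj_index, fraction=1.0):
    """(min, max) flux per reaction with the objective at its optimum."""
    vertices = enumerate_vertices(S, lb, ub)
    if not vertices:
        return None
    opt = max(v[obj_index] for v in vertices)
    threshold = opt * fraction if opt >= 0 else opt / fraction
    lb2 = lb.copy()
    lb2[obj_index] = max(lb2[obj_index], threshold)
    near_opt = enumerate_vertices(S, lb2, ub)
    n = S.shape[1]
    ranges = []
    for j in range(n):
        vals = [v[j] for v in near_opt]
        ranges.append((min(vals), max(vals)))
    return opt, ranges


def model_lp_data(model):
    S = build_stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    return S, lb, ub


# ---------------------------------------------------------------------------
# MOMA projection oracle (Dykstra's alternating projections)
# ---------------------------------------------------------------------------


def dykstra_moma(S, lb, ub, w, iterations=200000, tol=1e-13):
    """Euclidean projection of w onto {S v = 0} intersect [lb, ub].

    Dykstra's algorithm alternates projections onto the null-space of S and
    the bound box with correction terms; it converges to the exact
    projection for convex sets.
    """
    S = np.asarray(S, dtype=float)
    w = np.asarray(w, dtype=float)
    null = scipy.linalg.null_space(S) if S.size else np.eye(len(w))

    def proj_subspace(x):
        if null.size == 0:
            return np.zeros_like(x)
        return null @ (null.T @ x)

    x = w.copy()
    p = np.zeros_like(x)
    q = np.zeros_like(x)
    for _ in range(iterations):
        y = proj_subspace(x + p)
        p = x + p - y
        x_new = np.clip(y + q, lb, ub)
        q = y + q - x_new
        if np.linalg.norm(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    return x


# ---------------------------------------------------------------------------
# Reachability closure for gap detection
# ---------------------------------------------------------------------------


def reachability_producible(model):
    """Metabolite ids producible by forward/reverse firing closure.

    A reaction direction can fire once every metabolite it consumes is
    producible; products join the producible set (accumulation of
    by-products is allowed, matching the relaxed S.v >= 0 semantics).
    Exchange reactions with open uptake (lower bound < 0) seed the set.
    """
    producible = set()
    for rxn in model.reactions:
        if rxn.rtype == "exchange" and rxn.lower_bound < 0:
            producible |= set(rxn.stoichiometry)
    changed = True
    while changed:
        changed = False
        for rxn in model.reactions:
            subs_f = {m for m, c in rxn.stoichiometry.items() if c < 0}
            prods_f = {m for m, c in rxn.stoichiometry.items() if c > 0}
            if rxn.upper_bound > 0 and subs_f <= producible:
                if not prods_f <= producible:
                    producible |= prods_f
                    changed = True
            if rxn.lower_bound < 0 and prods_f <= producible:
                if not subs_f <= producible:
                    producible |= subs_f
                    changed = True
    return producible


def reachability_consumable(model, producible=None):
    """Metabolites some fireable reaction direction can drain."""
    if producible is None:
        producible = reachability_producible(model)
    consumable = set()
    for rxn in model.reactions:
        subs_f = {m for m, c in rxn.stoichiometry.items() if c < 0}
        prods_f = {m for m, c in rxn.stoichiometry.items() if c > 0}
        if rxn.rtype == "exchange" and rxn.upper_bound > 0:
            consumable |= subs_f  # secretion drains the extracellular pool
        if rxn.upper_bound > 0:
            for met in subs_f:
                if subs_f - {met} <= producible:
                    consumable.add(met)
        if rxn.lower_bound < 0:
            for met in prods_f:
                if prods_f - {met} <= producible:
                    consumable.add(met)
    return consumable


def reachability_blocked_reactions(model):
    """Reactions no direction of which can ever fire."""
    producible = reachability_producible(model)
    blocked = set()
    for rxn in model.reactions:
        subs_f = {m for m, c in rxn.stoichiometry.items() if c < 0}
        prods_f = {m for m, c in rxn.stoichiometry.items() if c > 0}
        fwd = rxn.upper_bound > 0 and subs_f <= producible
        rev = rxn.lower_bound < 0 and prods_f <= producible
        if not fwd and not rev:
            blocked.add(rxn.id)
    return blocked


# ---------------------------------------------------------------------------
# GPR truth table
# ---------------------------------------------------------------------------

_GENE_TOKEN = re.compile(r"[^\s(),]+")


def gpr_eval_python(expression: str, deleted: set) -> bool:
    """Evaluate a GPR with Python's own boolean evaluator."""
    if not expression.strip():
        return True

    def replace(match):
        token = match.group(0)
        low = token.lower()
        if low in ("and", "or"):
            return low
        return "False" if token in deleted else "True"

    text = _GENE_TOKEN.sub(replace, expression).replace(",", " or ")
    return bool(eval(text))  # noqa: S307 - controlled test input
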