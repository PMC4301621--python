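"""Linear-programming core: FBA, FVA, robustness scans and media handling.

All linear programs are solved with the deterministic HiGHS solver through
:func:`scipy.optimize.linprog`; repeated runs on the same model give
identical objective values. Flux vectors at degenerate optima are "an
optimal vertex" — only objective values are contract-stable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import UNBOUNDED, MetabolicModel, build_stoichiometric_matrix

FEASIBILITY_TOL = 1e-9

_STATUS_MAP = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded"}


class FbaError(RuntimeError):
    pass


@dataclass
class FluxDistribution:
    """One steady-state flux vector with its objective value and status."""

    fluxes: dict
    objective_value: Optional[float]
    status: str
    objective_id: Optional[str] = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class Medium:
    """Named set of exchange-reaction bound overrides.

    ``overrides`` maps exchange reaction id -> (lower, upper); uptake of
    magnitude u is encoded as lower bound -u. ``always_open`` lists
    exchange ids whose bounds are left untouched when the medium is applied
    (gases, water, protons and salts that every growth medium provides).
    """

    name: str
    overrides: dict = field(default_factory=dict)
    always_open: frozenset = frozenset()

    def with_override(self, reaction_id: str, lower: float, upper: float) -> "Medium":
        new = dict(self.overrides)
        new[reaction_id] = (lower, upper)
        return Medium(self.name, new, self.always_open)

    def without(self, reaction_id: str) -> "Medium":
        new = {k: v for k, v in self.overrides.items() if k != reaction_id}
        return Medium(self.name, new, self.always_open)


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a stated fraction of the optimum."""

    ranges: dict  # reaction id -> (min_flux, max_flux)
    fraction_of_optimum: float
    objective_value: float

    def __getitem__(self, reaction_id):
        return self.ranges[reaction_id]


@dataclass
class RobustnessCurve:
    """Objective optima along a scanned exchange uptake.

    Infeasible scan points are *absent* from ``values``/``objectives`` and
    recorded in ``infeasible_values``; they are never reported as zeros.
    """

    scanned_exchange: str
    values: list
    objectives: list
    infeasible_values: list
    constraints: dict = field(default_factory=dict)

    def peak(self):
        """(parameter, objective) at the maximal objective."""
        if not self.values:
            raise FbaError("robustness curve has no feasible points")
        k = int(np.argmax(self.objectives))
        return self.values[k], self.objectives[k]


# ---------------------------------------------------------------------------
# Media
# ---------------------------------------------------------------------------


def apply_medium(model: MetabolicModel, medium: Medium) -> MetabolicModel:
    """Copy of the model with exchange bounds set by the medium.

    Every exchange lower bound is first closed to 0 (no uptake) except for
    reactions in ``medium.always_open``; the explicit overrides are then
    applied. Secretion (upper bounds) is left open.
    """
    for rxn_id in medium.overrides:
        if not model.has_reaction(rxn_id):
            raise KeyError(f"medium override on unknown reaction {rxn_id!r}")
        if model.reaction(rxn_id).rtype != "exchange":
            raise ValueError(
                f"medium override on non-exchange reaction {rxn_id!r}"
            )
    new = model.copy()
    for rxn in new.reactions:
        if rxn.rtype != "exchange":
            continue
        if rxn.id in medium.always_open:
            continue
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    for rxn_id, (lo, hi) in medium.overrides.items():
        rxn = new.reaction(rxn_id)
        rxn.lower_bound = lo
        rxn.upper_bound = hi
    return new


def load_medium_preset(name: str) -> Medium:
    """Load a shipped medium preset (``mg``, ``ye``) by name."""
    ref = resources.files("oleaflux").joinpath(f"data/media/{name.lower()}.json")
    try:
        payload = json.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"no shipped medium preset named {name!r}") from None
    return medium_from_dict(payload)


def medium_from_dict(payload: dict) -> Medium:
    return Medium(
        name=payload["name"],
        overrides={k: tuple(v) for k, v in payload.get("overrides", {}).items()},
        always_open=frozenset(payload.get("always_open", [])),
    )


def medium_to_dict(medium: Medium) -> dict:
    return {
        "name": medium.name,
        "overrides": {k: list(v) for k, v in medium.overrides.items()},
        "always_open": sorted(medium.always_open),
    }


def load_carbon_screen_list() -> list:
    """Shipped list of carbon-source exchange ids for the utilization screen."""
    ref = resources.files("oleaflux").joinpath("data/media/carbon_screen.json")
    return json.loads(ref.read_text())["exchanges"]


# ---------------------------------------------------------------------------
# LP assembly
# ---------------------------------------------------------------------------


class _LinearProblem:
    """Cached S matrix and bound arrays for one model."""

    def __init__(self, model: MetabolicModel):
        self.model = model
        self.S = build_stoichiometric_matrix(model, sparse_format=True)
        self.lower = np.array([r.lower_bound for r in model.reactions], dtype=float)
        self.upper = np.array([r.upper_bound for r in model.reactions], dtype=float)
        self.rxn_ids = [r.id for r in model.reactions]

    def solve(self, c: np.ndarray, lower=None, upper=None):
        lo = self.lower if lower is None else lower
        hi = self.upper if upper is None else upper
        if np.any(lo > hi + FEASIBILITY_TOL):
            return None, "infeasible"
        res = linprog(
            c,
            A_eq=self.S,
            b_eq=np.zeros(self.S.shape[0]),
            bounds=np.column_stack([lo, np.maximum(lo, hi)]),
            method="highs",
        )
        status = _STATUS_MAP.get(res.status, "error")
        if status != "optimal":
            return None, status
        return res.x, "optimal"


def _objective_vector(problem: _LinearProblem, objective_id: str, direction: str):
    c = np.zeros(len(problem.rxn_ids))
    j = problem.model.reaction_index(objective_id)
    c[j] = -1.0 if direction == "max" else 1.0
    return c, j


def _bounds_with_constraints(
    problem: _LinearProblem,
    extra_constraints: Sequence[tuple] = (),
):
    lo = problem.lower.copy()
    hi = problem.upper.copy()
    for rxn_id, clo, chi in extra_constraints:
        j = problem.model.reaction_index(rxn_id)
        lo[j] = max(lo[j], clo)
        hi[j] = min(hi[j], chi)
    return lo, hi


# ---------------------------------------------------------------------------
# FBA / FVA / scans
# ---------------------------------------------------------------------------


def solve_fba(
    model: MetabolicModel,
    objective_id: Optional[str] = None,
    direction: str = "max",
    extra_constraints: Sequence[tuple] = (),
    _problem: Optional[_LinearProblem] = None,
) -> FluxDistribution:
    """Maximize (or minimize) one reaction flux subject to S·v = 0 and bounds.

    ``extra_constraints`` is a list of (reaction_id, lo, hi) tuples that
    tighten the model bounds for this solve only. Infeasibility and
    unboundedness are reported via ``status`` — never as silent zeros.
    """
    if direction not in {"max", "min"}:
        raise ValueError("direction must be 'max' or 'min'")
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise FbaError("no objective reaction set; refuse to solve")
    problem = _problem or _LinearProblem(model)
    c, j = _objective_vector(problem, objective_id, direction)
    lo, hi = _bounds_with_constraints(problem, extra_constraints)
    x, status = problem.solve(c, lo, hi)
    if status != "optimal":
        return FluxDistribution({}, None, status, objective_id)
    return FluxDistribution(
        dict(zip(problem.rxn_ids, x.tolist())), float(x[j]), "optimal", objective_id
    )


def solve_fba_fixed_growth(
    model: MetabolicModel,
    growth_rate: float,
    objective_id: str,
    direction: str = "max",
    biomass_id: Optional[str] = None,
) -> FluxDistribution:
    """FBA on ``objective_id`` with the biomass flux pinned to ``growth_rate``."""
    biomass_id = biomass_id or model.objective_id
    if biomass_id is None:
        raise FbaError("no biomass reaction identified for growth pinning")
    return solve_fba(
        model,
        objective_id,
        direction,
        extra_constraints=[(biomass_id, growth_rate, growth_rate)],
    )


def fva(
    model: MetabolicModel,
    reaction_ids: Optional[Iterable[str]] = None,
    fraction_of_optimum: float = 1.0,
    objective_id: Optional[str] = None,
) -> FVAResult:
    """Per-reaction flux ranges holding the objective at a fraction of optimum.

    Two LPs are solved per reaction after one base FBA. With the objective
    optimum z*: maximization problems require v_obj >= fraction·z* for
    z* >= 0 (and >= z*/fraction for z* < 0), mirroring the usual COBRA
    convention.
    """
    if not 0 < fraction_of_optimum <= 1:
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    objective_id = objective_id or model.objective_id
    problem = _LinearProblem(model)
    base = solve_fba(model, objective_id, _problem=problem)
    if not base.optimal:
        raise FbaError(f"base FBA is {base.status}; FVA aborted")
    opt = base.objective_value
    threshold = opt * fraction_of_optimum if opt >= 0 else opt / fraction_of_optimum
    j_obj = problem.model.reaction_index(objective_id)
    lo = problem.lower.copy()
    hi = problem.upper.copy()
    lo[j_obj] = max(lo[j_obj], threshold)
    ids = list(reaction_ids) if reaction_ids is not None else list(problem.rxn_ids)
    ranges = {}
    for rxn_id in ids:
        j = problem.model.reaction_index(rxn_id)
        c = np.zeros(len(problem.rxn_ids))
        c[j] = 1.0
        x_min, s1 = problem.solve(c, lo, hi)
        c[j] = -1.0
        x_max, s2 = problem.solve(c, lo, hi)
        if s1 != "optimal" or s2 != "optimal":
            raise FbaError(f"FVA subproblem for {rxn_id!r} is {s1}/{s2}")
        vmin, vmax = float(x_min[j]), float(x_max[j])
        if vmin > vmax:  # numerically crossed at a unique-flux reaction
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rxn_id] = (vmin, vmax)
    return FVAResult(ranges, fraction_of_optimum, opt)


def robustness_scan(
    model: MetabolicModel,
    scanned_exchange: str,
    values: Sequence[float],
    objective_id: str,
    min_growth: float = 0.0,
    biomass_id: Optional[str] = None,
) -> RobustnessCurve:
    """Optimal objective as one exchange uptake is pinned across a range.

    Each scan value u pins the exchange flux to exactly -u (uptake of
    magnitude u), requires biomass >= ``min_growth`` and maximizes the
    objective. Infeasible points are recorded as absent.
    """
    values = list(values)
    if not values:
        raise ValueError("empty scan value list")
    if any(b >= a for a, b in zip(values[1:], values)):
        raise ValueError("scan values must be strictly increasing")
    biomass_id = biomass_id or model.objective_id
    problem = _LinearProblem(model)
    feasible_values, objectives, infeasible = [], [], []
    for u in values:
        constraints = [(scanned_exchange, -u, -u)]
        if min_growth > 0 and biomass_id is not None:
            constraints.append((biomass_id, min_growth, np.inf))
        sol = solve_fba(
            model, objective_id, extra_constraints=constraints, _problem=problem
        )
        if sol.optimal:
            feasible_values.append(u)
            objectives.append(sol.objective_value)
        else:
            infeasible.append(u)
    return RobustnessCurve(
        scanned_exchange,
        feasible_values,
        objectives,
        infeasible,
        {"min_growth": min_growth, "objective": objective_id},
    )


def substrate_utilization_screen(
    model: MetabolicModel,
    base_medium: Medium,
    candidate_exchanges: Sequence[str],
    uptake: float = 1.0,
    growth_threshold: float = 1e-6,
    replaced_exchange: Optional[str] = None,
    objective_id: Optional[str] = None,
) -> list:
    """Sole-source growth screen.

    For each candidate exchange, the base medium is applied with
    ``replaced_exchange`` (the default source being substituted, if any)
    removed and the candidate opened at the stated uptake; growth means
    FBA biomass > ``growth_threshold``. Returns a list of
    ``(exchange_id, grows, growth_rate_or_None)`` rows.
    """
    for rxn_id in candidate_exchanges:
        if model.reaction(rxn_id).rtype != "exchange":
            raise ValueError(f"candidate {rxn_id!r} is not an exchange reaction")
    rows = []
    for rxn_id in candidate_exchanges:
        medium = base_medium
        if replaced_exchange is not None:
            medium = medium.without(replaced_exchange)
        medium = medium.with_override(rxn_id, -uptake, UNBOUNDED)
        sol = solve_fba(apply_medium(model, medium), objective_id)
        growth = sol.objective_value if sol.optimal else None
        rows.append((rxn_id, bool(growth is not None and growth > growth_threshold), growth))
    return rows
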