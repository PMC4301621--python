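"""Single-gene / single-reaction essentiality screens and their comparison.

A gene is called essential when its deletion drops the biomass optimum
below ``threshold`` times the wild-type optimum on the given medium (or
renders the LP infeasible). The default threshold is 1% of wild type; every
report records the threshold it used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .core import MetabolicModel
from .fba import FbaError, Medium, _LinearProblem, apply_medium, solve_fba

DEFAULT_THRESHOLD = 0.01


@dataclass
class EssentialityReport:
    """Per-entity knockout growth, ratio to wild type and essentiality call."""

    kind: str  # "gene" or "reaction"
    medium_name: str
    threshold: float
    wild_type_growth: float
    growth: dict  # entity id -> knockout growth (None if infeasible)
    ratio: dict  # entity id -> growth ratio (None if infeasible)
    call: dict  # entity id -> "essential" | "non-essential"
    subsystem: dict = field(default_factory=dict)

    @property
    def essential(self) -> set:
        return {k for k, v in self.call.items() if v == "essential"}

    @property
    def non_essential(self) -> set:
        return {k for k, v in self.call.items() if v == "non-essential"}

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "medium": self.medium_name,
            "threshold": self.threshold,
            "wild_type_growth": self.wild_type_growth,
            "n_total": len(self.call),
            "n_essential": len(self.essential),
        }


@dataclass
class EssentialityComparison:
    only_a: set
    only_b: set
    both: set
    subsystem_counts_a: dict
    subsystem_counts_b: dict


def _screen(
    model,
    medium,
    threshold,
    entities,
    blocked_reactions_for,
    kind,
    objective_id,
):
    conditioned = apply_medium(model, medium) if medium is not None else model.copy()
    problem = _LinearProblem(conditioned)
    wt = solve_fba(conditioned, objective_id, _problem=problem)
    if not wt.optimal or wt.objective_value <= 0:
        raise FbaError(
            f"medium {medium.name if medium else '<none>'!r} does not support "
            "growth; essentiality is undefined"
        )
    wt_growth = wt.objective_value
    growth, ratio, call, subsystem = {}, {}, {}, {}
    for entity in entities:
        blocked = blocked_reactions_for(entity)
        if blocked:
            saved = [
                (j, problem.lower[j], problem.upper[j])
                for j in (conditioned.reaction_index(rid) for rid in blocked)
            ]
            for j, _, _ in saved:
                problem.lower[j] = 0.0
                problem.upper[j] = 0.0
            sol = solve_fba(conditioned, objective_id, _problem=problem)
            for j, lb, ub in saved:
                problem.lower[j] = lb
                problem.upper[j] = ub
        else:
            sol = wt
        if sol.optimal:
            g = sol.objective_value
            growth[entity] = g
            ratio[entity] = g / wt_growth
            call[entity] = (
                "essential" if g / wt_growth < threshold else "non-essential"
            )
        else:  # infeasible knockouts count as essential
            growth[entity] = None
            ratio[entity] = None
            call[entity] = "essential"
        labels = sorted(
            {conditioned.reaction(rid).subsystem for rid in blocked}
            - {""}
        )
        subsystem[entity] = labels[0] if labels else ""
    return EssentialityReport(
        kind=kind,
        medium_name=medium.name if medium is not None else "<as-is>",
        threshold=threshold,
        wild_type_growth=wt_growth,
        growth=growth,
        ratio=ratio,
        call=call,
        subsystem=subsystem,
    )


def single_gene_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    threshold: float = DEFAULT_THRESHOLD,
    objective_id: Optional[str] = None,
) -> EssentialityReport:
    """Knock out every gene in turn and record the biomass optimum."""

    # precompute the reactions disabled by each single-gene deletion
    def blocked_for(gene):
        return [
            r.id
            for r in model.reactions
            if not r.gpr.is_empty and not r.gpr.evaluate({gene})
        ]

    return _screen(
        model, medium, threshold, list(model.genes), blocked_for, "gene", objective_id
    )


def single_reaction_deletion(
    model: MetabolicModel,
    medium: Optional[Medium] = None,
    threshold: float = DEFAULT_THRESHOLD,
    objective_id: Optional[str] = None,
    reaction_ids=None,
) -> EssentialityReport:
    """Block every reaction in turn (bounds (0, 0)) and record the optimum."""
    ids = list(reaction_ids) if reaction_ids is not None else [
        r.id for r in model.reactions
    ]
    return _screen(
        model, medium, threshold, ids, lambda rid: [rid], "reaction", objective_id
    )


def compare_essentiality(
    report_a: EssentialityReport, report_b: EssentialityReport
) -> EssentialityComparison:
    """Set differences and per-subsystem tallies between two screens."""
    if set(report_a.call) != set(report_b.call):
        raise ValueError("reports cover different universes")
    ess_a, ess_b = report_a.essential, report_b.essential

    def tally(entities, subsystems):
        counts: dict[str, int] = {}
        for e in entities:
            label = subsystems.get(e, "") or "<unassigned>"
            counts[label] = counts.get(label, 0) + 1
        return counts

    return EssentialityComparison(
        only_a=ess_a - ess_b,
        only_b=ess_b - ess_a,
        both=ess_a & ess_b,
        subsystem_counts_a=tally(ess_a, report_a.subsystem),
        subsystem_counts_b=tally(ess_b, report_b.subsystem),
    )
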