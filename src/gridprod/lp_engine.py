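"""LP primitives: flux maximization, L1 flux minimization, FVA, knockouts.

All solves run on the model's optlang/GLPK problem inside a cobrapy history
context, so the input model is never mutated and repeated calls on one model
are cheap (no model copies).  Infeasibility is a normal return value — the
grid search routinely produces infeasible cells — and only operations whose
signature cannot express emptiness raise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from optlang.symbolics import Zero

from .errors import GridProdError, InfeasibleProblemError, UnknownReactionError
from .model_core import FluxDistribution, MetabolicModel

__all__ = [
    "BoxConstraint",
    "LpOutcome",
    "maximize_flux",
    "minimize_total_flux",
    "flux_variability",
    "apply_knockouts",
]

_box_counter = itertools.count()


@dataclass(frozen=True)
class BoxConstraint:
    """An interval constraint ``lower <= v_reaction <= upper`` added to an LP."""

    reaction_id: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise GridProdError(
                f"box constraint on {self.reaction_id}: lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class LpOutcome:
    """Solver verdict plus the flux vector when one exists."""

    status: str  # optimal | infeasible | unbounded
    flux: FluxDistribution | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _add_boxes(model: MetabolicModel, extra: Iterable[BoxConstraint]) -> None:
    cm = model.cobra_model
    cons = []
    for bc in extra:
        rxn = model.require_reaction(bc.reaction_id)
        cons.append(
            cm.problem.Constraint(
                rxn.flux_expression,
                lb=bc.lower,
                ub=bc.upper,
                name=f"_box_{bc.reaction_id}_{next(_box_counter)}",
            )
        )
    if cons:
        cm.add_cons_vars(cons)


def _solve(model: MetabolicModel) -> str:
    model.cobra_model.solver.optimize()
    status = model.cobra_model.solver.status
    if status in ("optimal", "infeasible", "unbounded"):
        return status
    if status == "infeasible_or_unbounded":
        return "infeasible"
    raise GridProdError(f"LP solver returned unexpected status {status!r}")


def _extract_flux(model: MetabolicModel) -> FluxDistribution:
    cm = model.cobra_model
    values = {r.id: r.forward_variable.primal - r.reverse_variable.primal
              for r in cm.reactions}
    return FluxDistribution(values=values, objective_value=cm.solver.objective.value)


def maximize_flux(model: MetabolicModel, objective_id: str,
                  extra: Sequence[BoxConstraint] = ()) -> LpOutcome:
    """Maximize one reaction's flux over the steady-state polytope (FBA)."""
    model.require_reaction(objective_id)
    cm = model.cobra_model
    with cm:
        _add_boxes(model, extra)
        cm.objective = objective_id
        cm.objective_direction = "max"
        status = _solve(model)
        if status != "optimal":
            return LpOutcome(status=status)
        return LpOutcome(status="optimal", flux=_extract_flux(model))


def minimize_total_flux(model: MetabolicModel,
                        extra: Sequence[BoxConstraint] = ()) -> LpOutcome:
    """Minimize the total absolute flux Σ_j |v_j| (parsimonious LP).

    Exact LP reformulation: every flux is already split by optlang into
    non-negative forward and reverse parts, v = v+ - v-, and the objective
    minimizes Σ (v+ + v-).  At any optimum v+·v- = 0 per reaction, so the
    objective value equals Σ |v_j| over all reactions, exchanges included.
    """
    cm = model.cobra_model
    with cm:
        _add_boxes(model, extra)
        cm.objective = cm.problem.Objective(Zero, direction="min", sloppy=True)
        cm.objective.set_linear_coefficients(
            {v: 1.0 for r in cm.reactions for v in (r.forward_variable, r.reverse_variable)}
        )
        status = _solve(model)
        if status != "optimal":
            return LpOutcome(status=status)
        return LpOutcome(status="optimal", flux=_extract_flux(model))


def flux_variability(model: MetabolicModel, rxn_id: str,
                     extra: Sequence[BoxConstraint] = ()) -> tuple[float, float]:
    """Min and max attainable flux of one reaction under extra constraints.

    Raises :class:`InfeasibleProblemError` when the constrained feasible set
    is empty.  An unbounded direction is reported as ±inf.
    """
    model.require_reaction(rxn_id)
    cm = model.cobra_model
    out: list[float] = []
    with cm:
        _add_boxes(model, extra)
        cm.objective = rxn_id
        for direction, sentinel in (("min", -math.inf), ("max", math.inf)):
            cm.objective_direction = direction
            status = _solve(model)
            if status == "infeasible":
                raise InfeasibleProblemError(
                    f"no feasible flux for FVA of {rxn_id} under the given constraints"
                )
            out.append(sentinel if status == "unbounded" else cm.solver.objective.value)
    return out[0], out[1]


def apply_knockouts(model: MetabolicModel, rxn_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy with each listed reaction's bounds fixed to zero."""
    rxn_ids = set(rxn_ids)
    missing = [rid for rid in rxn_ids if rid not in model.cobra_model.reactions]
    if missing:
        raise UnknownReactionError(f"cannot knock out unknown reactions {sorted(missing)}")
    out = model.copy()
    for rid in rxn_ids:
        rxn = out.cobra_model.reactions.get_by_id(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out
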