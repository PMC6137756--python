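"""Grid search for parsimonious growth-coupled production designs.

The method tiles the rectangle [0, TMGR] x [0, TMPR] of growth rate (GR,
biomass flux) and production rate (PR, target exchange flux) into p_inv^2
cells, where TMGR/TMPR are the theoretical LP maxima of the two fluxes.  In
each cell two LPs run:

1. *first LP* — minimize total absolute flux subject to the cell's box
   constraints on GR and PR.  Reactions carrying negligible flux in this
   parsimonious solution (|v| below ``zero_tol``, excluding protected
   reactions) become the knockout candidate set R_not_used.
2. *second LP* — on the model with R_not_used forced to zero, maximize
   growth without any cell constraints; the production rate attained at that
   growth optimum (flux-variability min or max of the target with growth
   fixed at its maximum) is the cell's score, gated on the minimum viable
   growth rate.

The cell with the best score wins; its knockout set is the designed
network.  Cells are independent, so the score matrix does not depend on
evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GridProdError, UnboundedProblemError
from .lp_engine import (BoxConstraint, LpOutcome, flux_variability,
                        maximize_flux, minimize_total_flux)
from .model_core import FluxDistribution, MediumConfig, MetabolicModel

__all__ = [
    "GridConfig",
    "GridCell",
    "GridCellResult",
    "GridProdResult",
    "SecondLpResult",
    "compute_tmgr",
    "compute_tmpr",
    "protected_reactions",
    "first_lp",
    "extract_knockouts",
    "second_lp",
    "run_gridprod",
    "is_producible",
]

#: slack used when fixing growth at its LP maximum for the per-cell FVA
_FIX_TOL = 1e-9


@dataclass(frozen=True)
class GridConfig:
    """Algorithm parameters.

    p_inv is the number of grid divisions per axis (P = 1/p_inv); 25 is the
    resolution at which the production ability of the designs saturates on
    genome-scale models.  zero_tol is the cutoff below which a first-LP flux
    counts as unused; producible_tol the cutoff above which a final design
    counts as producing its target.  criterion selects whether the
    production rate reported at a growth optimum is the pessimistic (FVA
    minimum) or optimistic (FVA maximum) value.  literal_pr_gate stores a
    cell's score only when the production rate itself (rather than the
    growth rate) reaches min_growth; the default gates on growth.
    """

    p_inv: int = 25
    zero_tol: float = 1e-5
    producible_tol: float = 1e-5
    protect_exchanges: bool = True
    criterion: str = "fva_min"
    literal_pr_gate: bool = False

    def __post_init__(self) -> None:
        if self.p_inv < 1:
            raise ConfigurationError("p_inv must be a positive integer")
        if self.zero_tol <= 0 or self.producible_tol <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.criterion not in ("fva_min", "fva_max"):
            raise ConfigurationError(f"unknown criterion {self.criterion!r}")


@dataclass(frozen=True)
class GridCell:
    """One box [gr_lower, gr_upper] x [pr_lower, pr_upper] of the grid."""

    i: int
    j: int
    gr_lower: float
    gr_upper: float
    pr_lower: float
    pr_upper: float

    @classmethod
    def from_indices(cls, i: int, j: int, tmgr: float, tmpr: float,
                     p_inv: int) -> "GridCell":
        p = 1.0 / p_inv
        return cls(i=i, j=j,
                   gr_lower=tmgr * p * i, gr_upper=tmgr * p * (i + 1),
                   pr_lower=tmpr * p * j, pr_upper=tmpr * p * (j + 1))


@dataclass(frozen=True)
class SecondLpResult:
    """Outcome of the growth-maximizing LP on a knockout model."""

    gr: float
    pr: float
    status: str
    stored_pr: float


@dataclass(frozen=True)
class GridCellResult:
    cell: GridCell
    first_lp_status: str
    knockout_set: frozenset[str]
    second_lp_gr: float
    second_lp_pr: float
    stored_pr: float


@dataclass(frozen=True)
class GridProdResult:
    """The winning design plus the full score matrix."""

    best_cell: tuple[int, int]
    knockouts: frozenset[str]
    gr: float
    pr: float
    pr_fva_min: float
    pr_fva_max: float
    reactions_used: int
    pr_matrix: np.ndarray
    tmgr: float
    tmpr: float
    cells: list[GridCellResult] = field(repr=False, default_factory=list)


def compute_tmgr(model: MetabolicModel) -> float:
    """Theoretical maximum growth rate: LP maximum of the biomass flux."""
    out = maximize_flux(model, model.biomass_id)
    if out.status == "unbounded":
        raise UnboundedProblemError("biomass flux is unbounded; model lacks capacity limits")
    if not out.optimal:
        raise GridProdError(f"TMGR computation failed with status {out.status}")
    return out.flux.objective_value


def compute_tmpr(model: MetabolicModel, target_id: str | None = None) -> float:
    """Theoretical maximum production rate of the target.

    Computed with the biomass lower bound relaxed to zero: the production
    optimum may lie at zero growth, and the first LP is allowed to explore
    growth below the viability minimum.
    """
    target = target_id or model.target_id
    if target is None:
        raise ConfigurationError("no target reaction set")
    cm = model.cobra_model
    biomass = model.require_reaction(model.biomass_id)
    with cm:
        biomass.lower_bound = min(0.0, biomass.lower_bound)
        out = maximize_flux(model, target)
        if out.status == "unbounded":
            raise UnboundedProblemError("target flux is unbounded")
        if not out.optimal:
            raise GridProdError(f"TMPR computation failed with status {out.status}")
        return out.flux.objective_value


def protected_reactions(model: MetabolicModel, config: GridConfig) -> set[str]:
    """Reactions that are never knockout candidates.

    Biomass, target and maintenance are structural (removing them voids the
    design); exchange reactions are protected by default because the medium,
    not the designed network, decides what crosses the boundary.
    """
    protected = {model.biomass_id}
    if model.target_id:
        protected.add(model.target_id)
    if model.maintenance_id:
        protected.add(model.maintenance_id)
    if config.protect_exchanges:
        protected |= model.exchange_ids
    return protected


def first_lp(model: MetabolicModel, target_id: str | None,
             cell: GridCell) -> LpOutcome:
    """Parsimonious LP inside one grid cell.

    Minimizes total absolute flux subject to the cell's GR and PR boxes.
    The minimum-growth requirement is deliberately not imposed: designs
    found through transiently sub-viable flux patterns are legitimate as
    long as the *final* knockout network grows.
    """
    target = target_id or model.target_id
    boxes = [
        BoxConstraint(model.biomass_id, cell.gr_lower, cell.gr_upper),
        BoxConstraint(target, cell.pr_lower, cell.pr_upper),
    ]
    return minimize_total_flux(model, extra=boxes)


def extract_knockouts(flux: FluxDistribution, model: MetabolicModel,
                      config: GridConfig) -> frozenset[str]:
    """Unprotected reactions carrying negligible flux (R_not_used)."""
    protected = protected_reactions(model, config)
    return frozenset(
        rid for rid, v in flux.values.items()
        if abs(v) < config.zero_tol and rid not in protected
    )


def second_lp(model: MetabolicModel, knockouts: frozenset[str] | set[str],
              medium: MediumConfig, target_id: str | None = None,
              config: GridConfig | None = None) -> SecondLpResult:
    """Maximize growth on the knockout model and score the cell.

    The cell's box constraints are dropped; only the knockouts remain.  The
    production rate is the flux-variability value (per ``config.criterion``)
    of the target with growth fixed at its maximum.  ``stored_pr`` is that
    production rate when the viability gate passes (maximal growth at least
    ``medium.min_growth``), else 0.
    """
    config = config or GridConfig()
    target = target_id or model.target_id
    cm = model.cobra_model
    with cm:
        for rid in knockouts:
            model.require_reaction(rid).bounds = (0.0, 0.0)
        out = maximize_flux(model, model.biomass_id)
        if not out.optimal:
            return SecondLpResult(gr=0.0, pr=0.0, status=out.status, stored_pr=0.0)
        gr = out.flux.objective_value
        slack = _FIX_TOL * max(1.0, abs(gr))
        lo, hi = flux_variability(
            model, target,
            extra=[BoxConstraint(model.biomass_id, gr - slack, math.inf)],
        )
    pr = lo if config.criterion == "fva_min" else hi
    gate_value = pr if config.literal_pr_gate else gr
    stored = pr if gate_value >= medium.min_growth - 1e-9 else 0.0
    return SecondLpResult(gr=gr, pr=pr, status="optimal", stored_pr=stored)


def run_gridprod(model: MetabolicModel, target_id: str | None = None,
                 grid: GridConfig | None = None,
                 medium: MediumConfig | None = None,
                 cell_order: list[tuple[int, int]] | None = None) -> GridProdResult:
    """Run the full grid search and return the best design.

    The model must already have its medium applied and its target set.
    ``cell_order`` only changes the evaluation sequence (useful for testing
    order independence); the result is defined by a lexicographic argmax
    over (i, j) and does not depend on it.
    """
    grid = grid or GridConfig()
    medium = medium or MediumConfig()
    target = target_id or model.target_id
    if target is None:
        raise ConfigurationError("no target reaction set; call ensure_target_exchange first")
    model.require_reaction(target)

    tmgr = compute_tmgr(model)
    tmpr = compute_tmpr(model, target)
    if tmgr <= 0 or tmpr <= 0:
        raise GridProdError(
            f"nothing to grid: TMGR={tmgr:.6g}, TMPR={tmpr:.6g} (both must be positive)"
        )

    p = grid.p_inv
    order = cell_order if cell_order is not None else [(i, j) for i in range(p) for j in range(p)]
    pr_matrix = np.zeros((p, p))
    results: dict[tuple[int, int], GridCellResult] = {}

    for (i, j) in order:
        cell = GridCell.from_indices(i, j, tmgr, tmpr, p)
        first = first_lp(model, target, cell)
        if not first.optimal:
            res = GridCellResult(cell=cell, first_lp_status=first.status,
                                 knockout_set=frozenset(), second_lp_gr=0.0,
                                 second_lp_pr=0.0, stored_pr=0.0)
        else:
            knockouts = extract_knockouts(first.flux, model, grid)
            sec = second_lp(model, knockouts, medium, target, grid)
            res = GridCellResult(cell=cell, first_lp_status="optimal",
                                 knockout_set=knockouts, second_lp_gr=sec.gr,
                                 second_lp_pr=sec.pr, stored_pr=sec.stored_pr)
        results[(i, j)] = res
        pr_matrix[i, j] = res.stored_pr

    best_ij = (0, 0)
    best_val = -math.inf
    for i in range(p):
        for j in range(p):
            if pr_matrix[i, j] > best_val + 1e-12:
                best_val = pr_matrix[i, j]
                best_ij = (i, j)

    best = results[best_ij]
    cm = model.cobra_model
    with cm:
        for rid in best.knockout_set:
            model.require_reaction(rid).bounds = (0.0, 0.0)
        out = maximize_flux(model, model.biomass_id)
        # a design whose maximal growth misses the viability gate reports no
        # production, matching its zero stored score
        if out.optimal and out.flux.objective_value >= medium.min_growth - 1e-9:
            gr = out.flux.objective_value
            slack = _FIX_TOL * max(1.0, abs(gr))
            fva_min, fva_max = flux_variability(
                model, target,
                extra=[BoxConstraint(model.biomass_id, gr - slack, math.inf)],
            )
        else:
            gr = out.flux.objective_value if out.optimal else 0.0
            fva_min, fva_max = 0.0, 0.0

    cells_sorted = [results[ij] for ij in sorted(results)]
    return GridProdResult(
        best_cell=best_ij,
        knockouts=best.knockout_set,
        gr=gr,
        pr=best.stored_pr,
        pr_fva_min=fva_min,
        pr_fva_max=fva_max,
        reactions_used=len(model.cobra_model.reactions) - len(best.knockout_set),
        pr_matrix=pr_matrix,
        tmgr=tmgr,
        tmpr=tmpr,
        cells=cells_sorted,
    )


def is_producible(result: GridProdResult, which: str = "fva_min",
                  config: GridConfig | None = None) -> bool:
    """Whether the designed network's production rate clears the cutoff."""
    config = config or GridConfig()
    if which == "fva_min":
        value = result.pr_fva_min
    elif which == "fva_max":
        value = result.pr_fva_max
    else:
        raise ConfigurationError(f"unknown FVA criterion {which!r}")
    return value >= config.producible_tol
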