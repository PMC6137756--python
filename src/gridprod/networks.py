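"""Small test networks and exhaustive-search oracles.

* :func:`build_toy_network` — a fully determined 8-reaction, 3-metabolite
  network on which every step of the grid design procedure can be worked by
  hand.  Its structure makes the trade-off between growth and production
  sharp: at maximal growth the target is never produced unless the direct
  growth route (R3) is removed.
* :func:`random_network` — seeded random irreversible networks with a
  guaranteed feasible backbone, for property tests.
* :func:`brute_force_design` — enumerate every knockout subset; the ground
  truth any heuristic design must not beat.
* :func:`l1_minimum_by_enumeration` — total-absolute-flux minimum found by
  enumerating candidate basic solutions of the flux polytope; the ground
  truth for the parsimonious LP.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import cobra
import numpy as np
from cobra.util.array import create_stoichiometric_matrix

from .errors import ConfigurationError, GridProdError
from .grid_search import GridConfig, protected_reactions
from .lp_engine import BoxConstraint, flux_variability, maximize_flux
from .model_core import MediumConfig, MetabolicModel

__all__ = [
    "TOY_MIN_GROWTH",
    "toy_medium",
    "OracleResult",
    "build_toy_network",
    "random_network",
    "brute_force_design",
    "l1_minimum_by_enumeration",
]

#: minimum viable growth rate assumed for the toy network
TOY_MIN_GROWTH = 1.0


def toy_medium() -> MediumConfig:
    """Medium parameters for the toy network (only min_growth matters)."""
    return MediumConfig(min_growth=TOY_MIN_GROWTH)


@dataclass(frozen=True)
class OracleResult:
    """Best design found by exhaustive knockout enumeration."""

    best_knockouts: frozenset[str]
    gr: float
    pr: float
    criterion: str


def build_toy_network() -> MetabolicModel:
    """The 8-reaction toy network.

    Metabolites C1, C2, C3; reactions (bounds in brackets):

    ========  ==================  ==========  =======================
    id        conversion          bounds      role
    ========  ==================  ==========  =======================
    R1        -> C1               [0, 5]      source exchange
    R2        -> C1               [5, 5]      constant source
    R3        C1 -> C3            [0, 10]     internal
    R4        C1 -> C2            [0, 5]      internal
    R5        C3 -> C2            [0, 3]      internal
    R6        C2 ->               [0, 10]     target exchange
    R7        C3 ->               [0, 10]     biomass objective
    R8        C2 -> C3            [0, 1]      internal
    ========  ==================  ==========  =======================

    Maximal growth is 10 (all influx routed C1 -> C3 -> out through R3/R7)
    with zero production; maximal production is 8 (bottlenecked by R4 = 5
    and R5 = 3) at zero growth.  Removing R3 forces growth through the
    capacity-1 loop R8, giving the growth-coupled optimum (GR, PR) = (1, 4).
    """
    cm = cobra.Model("toy")
    c1 = cobra.Metabolite("C1", compartment="c")
    c2 = cobra.Metabolite("C2", compartment="c")
    c3 = cobra.Metabolite("C3", compartment="c")

    table = [
        ("R1", {c1: 1.0}, 0.0, 5.0),
        ("R2", {c1: 1.0}, 5.0, 5.0),
        ("R3", {c1: -1.0, c3: 1.0}, 0.0, 10.0),
        ("R4", {c1: -1.0, c2: 1.0}, 0.0, 5.0),
        ("R5", {c3: -1.0, c2: 1.0}, 0.0, 3.0),
        ("R6", {c2: -1.0}, 0.0, 10.0),
        ("R7", {c3: -1.0}, 0.0, 10.0),
        ("R8", {c2: -1.0, c3: 1.0}, 0.0, 1.0),
    ]
    reactions = []
    for rid, stoich, lb, ub in table:
        rxn = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        rxn.add_metabolites(stoich)
        reactions.append(rxn)
    cm.add_reactions(reactions)
    cm.objective = "R7"
    return MetabolicModel(cm, biomass_id="R7", target_id="R6")


def random_network(n_internal: int, n_reactions: int, seed: int) -> MetabolicModel:
    """A seeded random irreversible network that always supports growth.

    The network contains a throttleable source exchange and a constant
    source exchange (lower bound = upper bound, the maintenance-like forced
    influx that makes growth-coupled designs possible at all) feeding M1, a
    chain M1 -> M2 -> ... -> Mn (so biomass and target are always
    reachable), a biomass drain on Mn, a target drain on a random
    metabolite, and random internal conversions with integer stoichiometric
    coefficients in {1, 2} and integer capacities in [1, 10].  Integer data
    keep the LP vertices rational and the tests solver-stable.
    """
    if n_reactions < n_internal + 3:
        raise ConfigurationError(
            f"need n_reactions >= n_internal + 3, got {n_reactions} < {n_internal + 3}"
        )
    rng = np.random.default_rng(seed)
    cm = cobra.Model(f"random_{n_internal}m_{n_reactions}r_seed{seed}")
    mets = [cobra.Metabolite(f"M{k + 1}", compartment="c") for k in range(n_internal)]

    reactions = []

    def add(rid, stoich, ub):
        rxn = cobra.Reaction(rid, lower_bound=0.0, upper_bound=float(ub))
        rxn.add_metabolites(stoich)
        reactions.append(rxn)

    add("EX_src", {mets[0]: 1.0}, rng.integers(5, 11))
    const = float(rng.integers(1, 4))  # below the chain's minimum capacity
    const_rxn = cobra.Reaction("EX_const", lower_bound=const, upper_bound=const)
    const_rxn.add_metabolites({mets[0]: 1.0})
    reactions.append(const_rxn)
    for k in range(n_internal - 1):
        add(f"T{k + 1}", {mets[k]: -1.0, mets[k + 1]: 1.0}, rng.integers(3, 11))
    add("EX_bio", {mets[-1]: -1.0}, 10)
    target_met = int(rng.integers(0, n_internal))
    add("EX_tgt", {mets[target_met]: -1.0}, 10)

    # 2 sources + (n_internal - 1)-step chain + biomass + target = n_internal + 3
    n_extra = n_reactions - n_internal - 3
    for e in range(n_extra):
        a, b = rng.choice(n_internal, size=2, replace=False)
        ca, cb = rng.integers(1, 3), rng.integers(1, 3)
        add(f"R{e + 1}", {mets[a]: -float(ca), mets[b]: float(cb)},
            rng.integers(1, 11))

    cm.add_reactions(reactions)
    cm.objective = "EX_bio"
    return MetabolicModel(cm, biomass_id="EX_bio", target_id="EX_tgt")


def brute_force_design(model: MetabolicModel, target_id: str | None = None,
                       medium: MediumConfig | None = None,
                       criterion: str = "fva_min",
                       max_unprotected: int = 20) -> OracleResult:
    """Exhaustive knockout search: the ground-truth best design.

    Enumerates every subset of the unprotected reactions; for each, growth
    is maximized, subsets whose maximal growth falls below the viability
    minimum are discarded, and the target's FVA value (per ``criterion``)
    at fixed maximal growth scores the design.  Ties are broken toward the
    lexicographically smallest knockout set.
    """
    medium = medium or MediumConfig()
    target = target_id or model.target_id
    if target is None:
        raise ConfigurationError("no target reaction set")
    if criterion not in ("fva_min", "fva_max"):
        raise ConfigurationError(f"unknown criterion {criterion!r}")

    candidates = sorted(
        set(model.reaction_ids) - protected_reactions(model, GridConfig())
    )
    if len(candidates) > max_unprotected:
        raise GridProdError(
            f"{len(candidates)} unprotected reactions exceed the 2^k enumeration "
            f"guard of {max_unprotected}"
        )

    best: tuple[float, tuple[str, ...]] | None = None
    best_gr = 0.0
    cm = model.cobra_model
    for r in range(len(candidates) + 1):
        for subset in itertools.combinations(candidates, r):
            with cm:
                for rid in subset:
                    cm.reactions.get_by_id(rid).bounds = (0.0, 0.0)
                out = maximize_flux(model, model.biomass_id)
                if not out.optimal:
                    continue
                gr = out.flux.objective_value
                if gr < medium.min_growth - 1e-9:
                    continue
                slack = 1e-9 * max(1.0, abs(gr))
                lo, hi = flux_variability(
                    model, target,
                    extra=[BoxConstraint(model.biomass_id, gr - slack, math.inf)],
                )
            value = lo if criterion == "fva_min" else hi
            if best is None or value > best[0] + 1e-9 or (
                abs(value - best[0]) <= 1e-9 and subset < best[1]
            ):
                best = (value, subset)
                best_gr = gr

    if best is None:
        return OracleResult(best_knockouts=frozenset(), gr=0.0, pr=0.0,
                            criterion=criterion)
    return OracleResult(best_knockouts=frozenset(best[1]), gr=best_gr,
                        pr=best[0], criterion=criterion)


def l1_minimum_by_enumeration(model: MetabolicModel,
                              extra: list[BoxConstraint] | None = None,
                              ) -> tuple[float, np.ndarray] | None:
    """Minimum of Σ|v| over the flux polytope, by basic-solution enumeration.

    Independent of any LP solver: the stoichiometric matrix S (rank k) is
    read off the model, and every choice of n - k fluxes fixed at a bound
    (or at 0 for reversible fluxes, where |v| has a kink) yields a candidate
    point by solving the remaining square linear system.  All vertices of
    the sign-refined polytope arise this way, and the L1 objective attains
    its minimum at one of them when the polytope is bounded.

    Returns (minimal Σ|v|, argmin flux vector) or None when infeasible.
    Exponential in the reaction count — use on networks of ≲ 10 reactions.
    """
    cm = model.cobra_model
    S = create_stoichiometric_matrix(cm)
    rxn_ids = [r.id for r in cm.reactions]
    n = len(rxn_ids)
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    for bc in extra or []:
        idx = rxn_ids.index(bc.reaction_id)
        lb[idx] = max(lb[idx], bc.lower)
        ub[idx] = min(ub[idx], bc.upper)
    if np.any(lb > ub + 1e-12):
        return None
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise GridProdError("enumeration oracle requires finite bounds")

    k = np.linalg.matrix_rank(S, tol=1e-9)
    tol = 1e-8
    best_val = math.inf
    best_v: np.ndarray | None = None
    fix_values = [
        sorted({lb[idx], ub[idx]} | ({0.0} if lb[idx] < 0.0 < ub[idx] else set()))
        for idx in range(n)
    ]
    for free in itertools.combinations(range(n), k):
        fixed = [idx for idx in range(n) if idx not in free]
        A = S[:, free]
        for assignment in itertools.product(*(fix_values[idx] for idx in fixed)):
            v = np.empty(n)
            v[fixed] = assignment
            rhs = -S[:, fixed] @ np.asarray(assignment)
            sol, residual, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v[list(free)] = sol
            if np.max(np.abs(S @ v)) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            val = float(np.sum(np.abs(v)))
            if val < best_val - 1e-12:
                best_val = val
                best_v = v.copy()
    if best_v is None:
        return None
    return best_val, best_v
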