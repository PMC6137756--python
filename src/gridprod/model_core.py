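"""Metabolic model container, readers, and model preparation.

A model here is a thin annotated wrapper around a :class:`cobra.Model`:
cobrapy supplies the SBML-FBC / COBRA-JSON parsers, the stoichiometry
bookkeeping and the solver interface, while this package records which
reactions play the special roles the design algorithm needs (biomass
objective, target exchange, maintenance) and prepares the growth medium.

Sign convention: exchange reactions are written secretion-positive, so an
uptake rate of U mmol/gDW/h is enforced as exchange lower bound -U. This is
the orientation genome-scale SBML/JSON files are distributed in.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

import cobra
from cobra.util.solver import linear_reaction_coefficients

from .errors import ConfigurationError, ModelFormatError, UnknownReactionError

__all__ = [
    "MediumConfig",
    "MetabolicModel",
    "FluxDistribution",
    "load_model",
    "save_model",
    "apply_medium",
    "ensure_target_exchange",
]

#: Reaction-id dialects used by different releases of the E. coli
#: reconstructions on which the defaults are calibrated (BiGG old/new style).
GLUCOSE_EXCHANGE_IDS = ("EX_glc__D_e", "EX_glc_e", "EX_glc(e)", "EX_glc_D_e")
OXYGEN_EXCHANGE_IDS = ("EX_o2_e", "EX_o2(e)")
MAINTENANCE_IDS = ("ATPM", "ATPM(NGAM)")

_SOLVER = "glpk"


@dataclass(frozen=True)
class MediumConfig:
    """Growth-medium and minimum-growth parameters.

    Parameters
    ----------
    glc_uptake : float
        Glucose uptake rate cap (GUR), mmol/gDW/h.
    o2_uptake : float
        Oxygen uptake rate cap (OUR), mmol/gDW/h.  The default 5 models a
        microaerobic condition under which production yields tend to be
        higher than under full aeration.
    atp_maintenance : float
        Non-growth-associated ATP maintenance flux (NGAM), enforced as the
        lower bound of the maintenance reaction.
    min_growth : float
        Minimum viable growth rate; designs whose maximal growth falls below
        it are discarded.
    glc_exchange_id, o2_exchange_id, maintenance_id : str or None
        Explicit reaction ids; when None the usual id dialects are tried.
    free_externals : tuple of str
        Metabolite base names whose exchanges are never closed even though
        they contain carbon (freely diffusing externals such as CO2).
    """

    glc_uptake: float = 10.0
    o2_uptake: float = 5.0
    atp_maintenance: float = 8.39
    min_growth: float = 0.05
    glc_exchange_id: str | None = None
    o2_exchange_id: str | None = None
    maintenance_id: str | None = None
    free_externals: tuple[str, ...] = ("co2", "hco3")

    def __post_init__(self) -> None:
        for name in ("glc_uptake", "o2_uptake", "atp_maintenance", "min_growth"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model with role annotations.

    Wraps a :class:`cobra.Model` (stoichiometry, bounds, solver) and records
    the ids of the biomass objective, the production target exchange, and the
    maintenance reaction.  All preparation operations return new instances
    and never mutate their input.
    """

    cobra_model: cobra.Model
    biomass_id: str
    target_id: str | None = None
    maintenance_id: str | None = None

    def __post_init__(self) -> None:
        self.cobra_model.solver = _SOLVER
        # GLPK exposes only a feasibility tolerance; set it directly rather
        # than through Model.tolerance, which logs about the missing one
        self.cobra_model.solver.configuration.tolerances.feasibility = 1e-9
        if self.biomass_id not in self.cobra_model.reactions:
            raise ConfigurationError(f"biomass reaction {self.biomass_id!r} not in model")

    # -- convenience views -------------------------------------------------
    @property
    def reactions(self):
        return self.cobra_model.reactions

    @property
    def metabolites(self):
        return self.cobra_model.metabolites

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.cobra_model.reactions]

    @property
    def exchange_ids(self) -> set[str]:
        """Ids of boundary reactions (single-metabolite stoichiometry)."""
        return {r.id for r in self.cobra_model.reactions if r.boundary}

    def copy(self) -> "MetabolicModel":
        return replace(self, cobra_model=self.cobra_model.copy())

    def require_reaction(self, rxn_id: str) -> cobra.Reaction:
        try:
            return self.cobra_model.reactions.get_by_id(rxn_id)
        except KeyError as exc:
            raise UnknownReactionError(f"reaction {rxn_id!r} not in model") from exc


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state flux vector returned by an LP solve."""

    values: dict[str, float]
    objective_value: float

    def __getitem__(self, rxn_id: str) -> float:
        return self.values[rxn_id]


def _detect(model: cobra.Model, explicit: str | None, candidates: tuple[str, ...],
            what: str) -> str:
    if explicit is not None:
        if explicit not in model.reactions:
            raise ConfigurationError(f"{what} reaction {explicit!r} not in model")
        return explicit
    for rid in candidates:
        if rid in model.reactions:
            return rid
    raise ConfigurationError(
        f"no {what} reaction found; tried ids {list(candidates)}"
    )


def load_model(path: str | Path, format: str = "auto") -> MetabolicModel:
    """Read an SBML Level-3 FBC or COBRA JSON model file.

    The biomass reaction is taken from the declared objective.  A maintenance
    reaction is annotated when a standard ATPM id is present.
    """
    path = Path(path)
    if not path.exists():
        raise ModelFormatError(f"model file {path} does not exist")
    if format == "auto":
        format = "json" if path.suffix.lower() == ".json" else "sbml"
    try:
        if format == "json":
            cm = cobra.io.load_json_model(str(path))
        elif format == "sbml":
            cm = cobra.io.read_sbml_model(str(path))
        else:
            raise ConfigurationError(f"unknown model format {format!r}")
    except ConfigurationError:
        raise
    except Exception as exc:  # parser errors differ between backends
        raise ModelFormatError(f"could not parse {path} as {format}: {exc}") from exc

    objective = linear_reaction_coefficients(cm)
    if not objective:
        raise ConfigurationError(f"model {path} declares no objective reaction")
    biomass_id = max(objective, key=lambda r: abs(objective[r])).id
    maintenance = next((rid for rid in MAINTENANCE_IDS if rid in cm.reactions), None)
    return MetabolicModel(cm, biomass_id=biomass_id, maintenance_id=maintenance)


def save_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as COBRA JSON (the format derived models are kept in)."""
    cobra.io.save_json_model(model.cobra_model, str(path))


def _base_metabolite_name(met: cobra.Metabolite) -> str:
    """Strip the compartment tag from a metabolite id (both id dialects)."""
    return re.sub(r"(\(\w\)|_\w)$", "", met.id).lower()


def apply_medium(model: MetabolicModel, medium: MediumConfig) -> MetabolicModel:
    """Constrain the model to a glucose-limited minimal medium.

    Glucose is the sole carbon source: its exchange uptake is capped at
    ``glc_uptake``, oxygen at ``o2_uptake``, the maintenance reaction lower
    bound is set to ``atp_maintenance``, and every other carbon-containing
    exchange is closed to uptake.  Freely diffusing externals (CO2 by
    default) and non-carbon exchanges keep the file's own bounds.

    Idempotent; returns a new model.
    """
    out = model.copy()
    cm = out.cobra_model
    glc = _detect(cm, medium.glc_exchange_id, GLUCOSE_EXCHANGE_IDS, "glucose exchange")
    o2 = _detect(cm, medium.o2_exchange_id, OXYGEN_EXCHANGE_IDS, "oxygen exchange")
    atpm = _detect(cm, medium.maintenance_id or out.maintenance_id,
                   MAINTENANCE_IDS, "ATP maintenance")

    cm.reactions.get_by_id(glc).lower_bound = -medium.glc_uptake
    cm.reactions.get_by_id(o2).lower_bound = -medium.o2_uptake
    rxn_atpm = cm.reactions.get_by_id(atpm)
    rxn_atpm.lower_bound = medium.atp_maintenance
    if rxn_atpm.upper_bound < medium.atp_maintenance:
        rxn_atpm.upper_bound = math.inf

    free = {name.lower() for name in medium.free_externals}
    for rxn in cm.reactions:
        if not rxn.boundary or rxn.id == glc:
            continue
        met = next(iter(rxn.metabolites))
        elements = met.elements or {}
        if elements.get("C", 0) > 0 and _base_metabolite_name(met) not in free:
            if rxn.lower_bound < 0:
                rxn.lower_bound = 0.0
    out.maintenance_id = atpm
    return out


def ensure_target_exchange(model: MetabolicModel,
                           metabolite_or_reaction: str) -> tuple[MetabolicModel, str]:
    """Designate the production target, adding a secretion route if needed.

    If the argument names a reaction it becomes the target directly.  If it
    names a metabolite with an existing boundary exchange, that exchange is
    the target.  Otherwise a diffusion transport (compartment to
    extracellular) and an exchange reaction, both irreversible toward
    secretion with bounds [0, inf), are appended.
    """
    out = model.copy()
    cm = out.cobra_model
    name = metabolite_or_reaction
    if name in cm.reactions:
        out.target_id = name
        return out, name
    if name not in cm.metabolites:
        raise UnknownReactionError(f"{name!r} is neither a reaction nor a metabolite id")
    met = cm.metabolites.get_by_id(name)
    for rxn in met.reactions:
        if rxn.boundary:
            out.target_id = rxn.id
            return out, rxn.id
    # no secretion route: append diffusion transport + exchange
    ext = cobra.Metabolite(f"{met.id}__ext", name=f"{met.name or met.id} (extracellular)",
                           compartment="e", formula=met.formula, charge=met.charge)
    transport = cobra.Reaction(f"TD_{met.id}", lower_bound=0.0, upper_bound=math.inf)
    transport.add_metabolites({met: -1.0, ext: 1.0})
    exchange = cobra.Reaction(f"EX_{met.id}__ext", lower_bound=0.0, upper_bound=math.inf)
    exchange.add_metabolites({ext: -1.0})
    cm.add_reactions([transport, exchange])
    out.target_id = exchange.id
    return out, exchange.id
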