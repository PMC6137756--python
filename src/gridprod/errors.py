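"""Exception hierarchy for gridprod."""


class GridProdError(Exception):
    """Base class for all gridprod errors."""


class ModelFormatError(GridProdError):
    """A model file could not be parsed as SBML-FBC or COBRA JSON."""


class ConfigurationError(GridProdError):
    """A required reaction/parameter is missing or inconsistent."""


class UnknownReactionError(GridProdError, KeyError):
    """A reaction or metabolite id is not present in the model."""


class InfeasibleProblemError(GridProdError):
    """An LP whose caller requires a feasible region found none.

    Only raised by operations (such as flux variability analysis) where an
    empty feasible set cannot be expressed as a normal return value.
    """


class UnboundedProblemError(GridProdError):
    """An LP objective is unbounded, i.e. the model lacks capacity limits."""
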