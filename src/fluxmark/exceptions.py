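"""Exception hierarchy.

All package errors derive from :class:`FluxmarkError` so callers can catch
one base class; the subclasses distinguish structural problems in an input
model from configuration mistakes and from numerical/solver failures.
"""


class FluxmarkError(Exception):
    """Base class for all errors raised by fluxmark."""


class StructureError(FluxmarkError):
    """A model file or object violates a structural invariant
    (dangling metabolite/gene reference, empty reaction list, ...)."""


class ConfigError(FluxmarkError):
    """Invalid configuration: bad parameter value, missing biomass
    reaction, a medium entry that is not an exchange reaction, ..."""


class GPRParseError(FluxmarkError):
    """A gene-protein-reaction rule string could not be parsed."""


class SolverError(FluxmarkError):
    """The LP solver returned a non-optimal status where one was required."""


class InfeasibleError(SolverError):
    """A required growth rate or reduction target is infeasible."""


class SearchError(FluxmarkError):
    """A parameter search (e.g. for the TRFBA saturation point) failed to
    bracket its target within the allowed range."""


class GenerationError(FluxmarkError):
    """A synthetic-network specification produced an invalid model
    (typically one that cannot grow under its own medium)."""
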