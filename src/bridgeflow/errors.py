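"""Exception hierarchy for bridgeflow."""


class BridgeflowError(Exception):
    """Base class for all package errors."""


class InputError(BridgeflowError):
    """Malformed or inconsistent user input (files, arguments)."""


class CohortValidationError(InputError):
    """A cohort record violates a physical invariant; names the offending row."""


class StatsError(BridgeflowError):
    """Degenerate input to a statistical routine."""


class MomentMatchError(BridgeflowError):
    """Requested truncated-normal moments are not attainable within the bounds."""


class GeometryError(BridgeflowError):
    """Infeasible junction parameter combination."""


class ResolutionError(BridgeflowError):
    """Grid spacing too coarse for the requested geometry."""


class RegimeError(BridgeflowError):
    """Flow conditions outside the laminar regime the solver is valid for."""


class AnalysisError(BridgeflowError):
    """WSS post-processing could not be carried out (e.g. empty plateau window)."""
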