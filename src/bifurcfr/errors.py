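"""Exception types shared across the package."""


class BifurcfrError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BifurcfrError, ValueError):
    """A physical or numerical parameter is outside its admissible range."""


class ConstructionError(BifurcfrError):
    """A geometric construction is infeasible for the requested parameters."""


class TessellationError(BifurcfrError):
    """Surface triangulation failed validation (open edges, self-contact...)."""


class ProbeError(BifurcfrError):
    """A cross-section probe could not be extracted from the flow field."""


class FitError(BifurcfrError):
    """A statistical fit is under-determined or singular."""
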