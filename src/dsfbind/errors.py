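"""Exception hierarchy.

Everything raised on bad user input or unprocessable data derives from
:class:`DSFError`, so callers (and the CLI) can distinguish domain failures
from programming errors.
"""


class DSFError(Exception):
    """Base class for all dsfbind domain errors."""


class PlateFormatError(DSFError):
    """A plate or plate-map file does not conform to the expected dialect."""


class PlateValidationError(DSFError):
    """Structurally well-formed input violates a semantic invariant."""


class ParameterError(DSFError):
    """An analysis parameter is out of its valid range."""


class DegenerateCurveError(DSFError):
    """A melt trace carries no usable signal (e.g. constant fluorescence)."""


class NoTransitionError(DSFError):
    """No unfolding transition could be located in a derivative trace."""


class NotBiphasicError(DSFError):
    """Biphasic analysis was requested but only one transition is resolvable."""


class FitError(DSFError):
    """A model fit failed to converge or returned inadmissible parameters."""
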