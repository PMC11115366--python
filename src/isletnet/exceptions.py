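"""Exception hierarchy for isletnet.

All errors raised by the library derive from :class:`IsletNetError` so that
callers can catch everything with a single ``except`` clause.  Errors that
are fundamentally bad parameter values also derive from :class:`ValueError`.
"""


class IsletNetError(Exception):
    """Base class for all isletnet errors."""


class ParameterError(IsletNetError, ValueError):
    """An argument value is outside its documented domain."""


class InvalidFilterError(ParameterError):
    """Band-pass cutoffs are incompatible with the sampling frequency."""


class ShortSeriesError(IsletNetError, ValueError):
    """A time series is too short for the requested operation."""


class ConstructionError(IsletNetError):
    """A network-construction method could not satisfy its contract."""


class PackingError(IsletNetError):
    """Cell placement failed: too many cells for the disc at the
    requested minimum spacing."""


class InputError(IsletNetError, ValueError):
    """Inputs to a multi-object operation are mutually inconsistent
    (e.g. two networks over different cell sets)."""
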