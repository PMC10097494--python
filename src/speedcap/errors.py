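"""Exception hierarchy shared across the package.

All errors raised by speedcap derive from :class:`SpeedCAPError` so callers
can catch the package's failures with a single ``except`` clause while still
distinguishing structural problems (malformed containers), parameter
problems (out-of-range settings) and degenerate inputs (data for which the
requested quantity is mathematically undefined).
"""


class SpeedCAPError(Exception):
    """Base class for all speedcap errors."""


class StructuralError(SpeedCAPError):
    """A container violates its structural invariants (missing frame,
    mismatched lengths, wrong mask shape, ...)."""


class ParameterError(SpeedCAPError, ValueError):
    """A user-supplied setting is outside its documented range."""


class DegenerateInputError(SpeedCAPError):
    """Input for which the requested quantity is undefined
    (all-zero matrix, zero normalizer, zero variance, ...)."""


class UndefinedCorrelationError(DegenerateInputError):
    """Correlation requested on data with zero variance after demeaning."""


class FormatError(SpeedCAPError):
    """A file does not conform to the documented on-disk format."""
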