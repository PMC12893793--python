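"""Exception hierarchy.

All popax errors derive from :class:`PopaxError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the matching builtin so generic handling keeps working.
"""


class PopaxError(Exception):
    """Base class for all popax errors."""


class ParameterError(PopaxError, ValueError):
    """An argument is outside its documented domain."""


class ShapeError(PopaxError, ValueError):
    """Array shapes or cell axes do not line up."""


class InsufficientDataError(PopaxError, ValueError):
    """Too few trials/repeats for the requested computation."""


class DegenerateBasisError(PopaxError, ValueError):
    """The decoding basis cannot be constructed (zero dU, rank-0 noise)."""


class ConfigurationError(PopaxError, ValueError):
    """A configuration (windowing, frame rate) yields an empty computation."""


class BoundsError(PopaxError, IndexError):
    """An event or window falls outside the recorded trace."""


class NumericError(PopaxError, ArithmeticError):
    """A numerically invalid quantity was requested (e.g. non-PSD covariance)."""
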