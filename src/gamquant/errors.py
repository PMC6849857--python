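"""Exception hierarchy for gamquant.

All errors raised by the package derive from :class:`GamquantError`, so
callers can catch a single base class at pipeline level while tests can
assert on the specific failure mode.
"""


class GamquantError(Exception):
    """Base class for all gamquant errors."""


class ParameterError(GamquantError, ValueError):
    """A specification or function parameter is outside its valid range."""


class InputError(GamquantError, ValueError):
    """Input data is missing, empty, or malformed."""


class ConfigurationError(GamquantError, ValueError):
    """A configuration object (stain matrix, run config) is invalid."""


class DegenerateHistogramError(GamquantError):
    """A histogram has fewer than two non-empty bins, so no threshold exists."""


class EmptyTissueError(GamquantError):
    """No tissue pixels remain after masking/exclusion."""


class DegenerateSplitError(GamquantError):
    """A marker cannot be dichotomized (all values equal / no admissible cut)."""


class UndefinedStatisticError(GamquantError):
    """A statistic is undefined for the given data (constant input, no events)."""
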