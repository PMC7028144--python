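"""Exception hierarchy.

All estimator failures derive from :class:`RootKineticsError` so batch
drivers can collect per-root failures without aborting a cohort.
"""


class RootKineticsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RootKineticsError, ValueError):
    """An input parameter violates a stated invariant."""


class DomainError(RootKineticsError, ValueError):
    """A value lies outside the mathematical domain of an operation."""


class InsufficientDataError(RootKineticsError, ValueError):
    """Too few observations to attempt the operation."""


class SegmentationError(RootKineticsError, RuntimeError):
    """A cell-length profile could not be segmented by the stated rule."""


class BoundaryNotFoundError(RootKineticsError, RuntimeError):
    """The plateau rule matched no point of the series."""


class EstimationError(RootKineticsError, RuntimeError):
    """A profile estimator could not produce a usable fit."""


class AnchorEstimationError(RootKineticsError, RuntimeError):
    """No usable 2C mode found in a fluorescence-intensity sample."""


class ConfigError(RootKineticsError, ValueError):
    """A pipeline configuration is malformed."""
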