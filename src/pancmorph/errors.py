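"""Exception hierarchy.

Every error raised on a user-facing code path derives from :class:`PancmorphError`
so callers (and the CLI) can distinguish pipeline failures from bugs.
"""


class PancmorphError(Exception):
    """Base class for all pancmorph errors."""


class ParameterError(PancmorphError, ValueError):
    """An argument is outside its validated range."""


class SizingError(PancmorphError, ValueError):
    """A grid is too small to contain the requested phantom."""


class GeometryError(PancmorphError, ValueError):
    """An ROI/polygon is invalid, out of bounds, or incorrectly nested."""


class EmptySegmentationError(PancmorphError, ValueError):
    """A mask or silhouette has no foreground; flags a missing organ, distinct
    from a legitimate zero measurement."""


class ConfigurationError(PancmorphError, ValueError):
    """Analysis configuration cannot yield a reliable estimate
    (e.g. too few box sizes for a stable log-log slope)."""


class InputError(PancmorphError, ValueError):
    """Malformed or inconsistent input data (mismatched echo shapes,
    wrong number of slice means, duplicate ids...)."""


class ConstraintError(PancmorphError, RuntimeError):
    """A stochastic constraint could not be satisfied within the attempt cap."""
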