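"""Exception types shared across the package."""


class RingScaleError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RingScaleError, ValueError):
    """A configuration value violates its invariants."""


class EmptyMaskError(RingScaleError, ValueError):
    """An operation received an empty cell mask or empty pixel set."""


class NoForegroundError(RingScaleError, ValueError):
    """Hysteresis segmentation found no voxel above the high threshold."""


class InsufficientDataError(RingScaleError, ValueError):
    """Too few observations for the requested fit."""


class CollinearityError(RingScaleError, ValueError):
    """Regression design matrix is rank deficient."""


class DegenerateFitError(RingScaleError, ValueError):
    """Geometric fit is singular (e.g. circle fit to collinear points)."""


class RenderError(RingScaleError, ValueError):
    """A synthetic scene cannot be rendered with the given geometry."""
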