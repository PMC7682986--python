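"""Exception types shared across the pipeline stages."""


class PolarimapError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(PolarimapError, ValueError):
    """A synthetic-data specification violates its invariants."""


class InvalidTransformError(PolarimapError, ValueError):
    """A rotation in an applied-transform chain is not orthonormal."""


class EmptyFilamentError(PolarimapError, ValueError):
    """A filament with zero segments was passed to the majority vote."""


class UndefinedScoreError(PolarimapError, ValueError):
    """Bundle polarity score requested with no neighbor relations (MPs + UPs = 0)."""


class SchemaError(PolarimapError, ValueError):
    """A segment table is missing a required column or contains invalid values."""


class FitFailureError(PolarimapError, RuntimeError):
    """Nonlinear least squares failed to converge; carries diagnostics."""
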