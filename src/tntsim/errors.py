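"""Exception hierarchy.

All package errors derive from :class:`TntError` so callers can catch one
base class; the subclasses distinguish configuration mistakes from numerical
failures and bad measurement inputs.
"""


class TntError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(TntError):
    """Geometry cannot be rasterized at the requested grid resolution
    (e.g. a nanochannel narrower than one cell after rounding)."""


class ConfigurationError(TntError):
    """Invalid or incomplete configuration (unknown key, missing material,
    out-of-range value)."""


class SolverError(TntError):
    """The potential solver failed to converge; carries the final residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class AnalysisError(TntError):
    """A measurement record is unusable (empty response window, no trials,
    non-positive denominator)."""


class InputError(TntError):
    """Malformed data input (empty stack, degenerate ROI polygon)."""


class GenerationError(TntError):
    """Synthetic-data generation failed (e.g. object packing infeasible)."""
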