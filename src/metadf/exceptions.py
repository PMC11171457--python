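"""Exception hierarchy for the metadf package."""


class MetadfError(Exception):
    """Base class for all package errors."""


class ParameterError(MetadfError, ValueError):
    """Invalid parameter values or orderings."""


class DomainError(MetadfError, ValueError):
    """Coordinate outside the landscape domain."""


class IntegrationError(MetadfError, RuntimeError):
    """Non-finite force or diverged trajectory during sampling."""


class EmptyProfileError(MetadfError, ValueError):
    """All samples were discarded or no bin received data."""


class ConsistencyError(MetadfError, ValueError):
    """Mismatched metadata (e.g. temperatures) across traces."""


class GapError(MetadfError, ValueError):
    """A run of empty interior bins too long to interpolate across."""

    def __init__(self, msg, interval=None):
        super().__init__(msg)
        self.interval = interval


class BulkReferenceError(MetadfError, ValueError):
    """PMF not referenced to zero in the bulk window."""


class DecompositionError(MetadfError, ValueError):
    """Mode decomposition failed (fewer than two local minima)."""

    def __init__(self, msg, single_mode=None):
        super().__init__(msg)
        self.single_mode = single_mode


class DegenerateScaleError(MetadfError, ZeroDivisionError):
    """Coverage scale is degenerate (R_ct∞ equals the blank R_ct0)."""


class FitError(MetadfError, RuntimeError):
    """Nonlinear fit failed to converge."""


class SpeedupDiagnosticError(MetadfError, RuntimeError):
    """The force-integration arm itself failed to converge within budget."""


class SelectionError(MetadfError, ValueError):
    """Atom selection matched nothing."""


class ConfigError(MetadfError, ValueError):
    """Invalid or unknown configuration keys."""
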