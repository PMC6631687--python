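"""Exception hierarchy shared across the pipeline."""


class IvivekitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(IvivekitError, ValueError):
    """Raised when an operation's preconditions are violated."""


class FitFailureError(IvivekitError, RuntimeError):
    """A nonlinear fit did not reach a usable optimum.

    Carries the best attempt (if any) in ``diagnostics`` so callers can
    inspect what went wrong instead of silently accepting a bad fit.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DataQualityError(IvivekitError, ValueError):
    """Measured data violate a physical bound (not silently clamped)."""


class GeneratorConfigError(IvivekitError, ValueError):
    """Synthetic-data generator asked for mutually inconsistent truths."""


class CrossReferenceError(IvivekitError, KeyError):
    """A compound id present in one input table is missing from another."""

    def __init__(self, missing, where: str):
        self.missing = sorted(missing)
        self.where = where
        super().__init__(
            f"compound(s) {', '.join(self.missing)} missing from {where}"
        )
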