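"""Exception hierarchy for renalpk.

All package-raised errors derive from :class:`RenalPKError` so callers can
catch pipeline failures without masking programming errors.
"""


class RenalPKError(Exception):
    """Base class for all renalpk errors."""


class ValidationError(RenalPKError, ValueError):
    """A parameter set, table or argument violated its invariants."""


class IntegrationError(RenalPKError, RuntimeError):
    """The ODE integrator produced non-finite or negative state."""


class NoValidFitError(RenalPKError):
    """No terminal log-linear window yields a positive elimination slope.

    Downstream, quantities that need lambda_z (AUC_inf, CL_tot) are then
    reported as not calculable rather than propagating the exception.
    """


class CoverageError(RenalPKError, ValueError):
    """Urine collection intervals do not cover the requested window."""

    def __init__(self, missing_spans):
        self.missing_spans = list(missing_spans)
        spans = ", ".join(f"[{a:g}, {b:g}] min" for a, b in self.missing_spans)
        super().__init__(f"urine intervals leave the window uncovered on: {spans}")


class UndefinedRatioError(RenalPKError, ZeroDivisionError):
    """A ratio-type statistic has a non-positive denominator."""


class SchemaError(RenalPKError, ValueError):
    """A CSV file does not conform to its declared schema."""


class LayoutError(RenalPKError, ValueError):
    """Results are incomplete for the requested report layout."""
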