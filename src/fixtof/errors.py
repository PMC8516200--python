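"""Exception hierarchy for fixtof.

Every error raised deliberately by the package derives from
:class:`FixtofError`, so callers (and the CLI) can distinguish domain
failures from programming errors.
"""


class FixtofError(Exception):
    """Base class for all fixtof domain errors."""


class MalformedTraceError(FixtofError):
    """A TOF trace violates its invariants (e.g. a time with no readings)."""


class InsufficientDataError(FixtofError):
    """Too few data points for the requested fit or confidence interval."""


class NonIdentifiableError(FixtofError):
    """The decay constant cannot be identified (e.g. constant signal)."""


class FitFailureError(FixtofError):
    """The nonlinear least-squares solver did not converge.

    Carries solver diagnostics in ``.diagnostics`` when available.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InvalidFitError(FixtofError):
    """A fit object violates its invariants (e.g. non-positive tau)."""


class InvalidArgumentError(FixtofError):
    """An argument is outside its mathematical domain."""


class OrderingError(FixtofError):
    """A streamed time point does not exceed previously seen times."""


class NoTissueError(FixtofError):
    """Tissue segmentation produced an empty mask."""


class NoAnalyzableTissueError(FixtofError):
    """Non-staining exclusion removed the entire tissue footprint."""


class ConfigError(FixtofError):
    """Invalid or unknown configuration (e.g. collinear stain vectors)."""


class ParseError(FixtofError):
    """An input file is missing columns, calibration, or is malformed."""
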