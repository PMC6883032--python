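"""Exception hierarchy shared across the pipeline stages."""


class TidalCarbonError(Exception):
    """Base class for all package errors."""


class ValidationError(TidalCarbonError, ValueError):
    """An input value violates a documented precondition."""


class ConfigurationError(TidalCarbonError, ValueError):
    """A configuration object is internally inconsistent."""


class SchemaError(TidalCarbonError, ValueError):
    """A CSV table is missing a mandatory column or has the wrong shape."""


class RowParseError(TidalCarbonError, ValueError):
    """A CSV row holds an unparseable value; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class EmptyProfileError(TidalCarbonError, ValueError):
    """No sediment layer intersects the averaging window."""


class TrendUnavailableError(TidalCarbonError):
    """A tide-gauge series has insufficient coverage for the requested window.

    Deliberately distinct from numerical failures: callers route these
    gauges to the short-record bridge instead of aborting.
    """


class StageError(TidalCarbonError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
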