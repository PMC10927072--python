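"""Exception hierarchy for scgeom."""


class ScgeomError(Exception):
    """Base class for all scgeom errors."""


class FormatError(ScgeomError):
    """A file could not be parsed; the message names the offending content."""


class ConsistencyError(ScgeomError):
    """Input pieces disagree (e.g. matrix dimensions vs. id lists, duplicate ids)."""


class DegenerateInputError(ScgeomError):
    """Input is too small or too degenerate for the operation."""


class DegenerateOutputError(ScgeomError):
    """An operation removed or collapsed everything (e.g. QC filtered all cells)."""


class DegenerateCurveError(ScgeomError):
    """A curve that must be normalized is identically zero."""


class GenerationError(ScgeomError):
    """A simulator could not satisfy its constraints within bounded retries."""


class NumericalError(ScgeomError):
    """A numerical routine (eigendecomposition, ...) failed."""


class StateError(ScgeomError):
    """An object was used before being fitted/initialized."""


class MetricError(ScgeomError):
    """A single scoring metric failed; carries the metric name."""

    def __init__(self, metric: str, cause: Exception):
        self.metric = metric
        self.cause = cause
        super().__init__(f"metric {metric!r} failed: {cause}")
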