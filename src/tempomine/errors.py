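"""Exception hierarchy shared by all tempomine modules."""


class TempomineError(Exception):
    """Base class for all errors raised by tempomine."""


class SchemaError(TempomineError):
    """A corpus record violates the expected schema (missing/invalid field)."""


class TimestampParseError(TempomineError):
    """A timestamp string could not be parsed into a datetime."""


class ParameterError(TempomineError, ValueError):
    """An operation was called with an out-of-range or inconsistent parameter."""


class AlignmentError(TempomineError):
    """External-timeline alignment failed (missing anchor or timestamp)."""


class ConsistencyError(TempomineError):
    """Inputs that must agree (e.g. spans and their source text) do not."""


class OrderingError(TempomineError, ValueError):
    """A time interval was given with its end before its start."""


class ModeError(TempomineError):
    """A processing mode was requested that the inputs cannot support."""


class ValidationError(TempomineError):
    """A configuration object failed validation; the message names the field."""


class StageError(TempomineError):
    """A pipeline stage failed; carries the stage name and partial manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict | None = None):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.manifest = manifest or {}
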