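"""Exception hierarchy shared across the pipeline.

Validation/format/domain problems map to CLI exit code 2, inference
failures (e.g. a fully degenerate bootstrap) to exit code 3.
"""


class EcoprsError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EcoprsError):
    """A file could not be parsed (bad schema, ragged rows, unparseable numbers)."""


class ValidationError(EcoprsError):
    """Parsed content violates an invariant (bounds, duplicates, empty input)."""


class DomainError(EcoprsError):
    """An argument is outside the mathematical domain of an operation."""


class DegenerateInputError(DomainError):
    """A statistic is undefined for the given data (e.g. a constant vector)."""


class InferenceError(EcoprsError):
    """A resampling procedure could not produce a usable distribution."""


class PipelineError(EcoprsError):
    """A pipeline stage failed; wraps the original error with stage context."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
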