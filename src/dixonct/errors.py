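"""Exception hierarchy shared across the package."""


class DixonCTError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DixonCTError):
    """A file could not be parsed as a supported image format."""


class CohortError(DixonCTError):
    """The mDixon channel volumes do not share a common grid."""


class PreconditionError(DixonCTError, ValueError):
    """An operation was called with inputs violating its contract."""


class DegenerateInputError(DixonCTError, ValueError):
    """Input lacks the structure the algorithm needs (e.g. constant image)."""


class AmbiguityError(DixonCTError):
    """The input admits no unique interpretation (ties, multiple series)."""


class PipelineStageError(DixonCTError):
    """A pipeline stage failed; the message names the stage."""
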