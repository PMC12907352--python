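"""Exception hierarchy used across the package."""


class PlayseqError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PlayseqError):
    """A file or table does not have the expected structure."""


class RecordError(PlayseqError):
    """A single record is invalid (carries row/record context in the message)."""


class ParameterError(PlayseqError, ValueError):
    """An argument is outside its documented domain."""


class SeparationError(PlayseqError):
    """Complete separation in a logistic fit; coefficients are unbounded."""


class StageError(PlayseqError):
    """A pipeline stage failed; message names the stage and the cause."""
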