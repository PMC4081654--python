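"""Exception hierarchy shared across the pipeline.

All user-facing errors derive from :class:`StressmemError` so the CLI can map
them onto exit codes (validation problems -> 2, stage failures -> 3).
"""


class StressmemError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(StressmemError):
    """A file does not conform to its declared tabular dialect."""


class ValidationError(StressmemError, ValueError):
    """Well-formed input whose values violate a domain invariant."""


class StageError(StressmemError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
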