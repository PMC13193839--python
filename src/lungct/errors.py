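"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI lives in :mod:`lungct.cli`; library code raises
these types and never calls ``sys.exit``.
"""


class LungCTError(Exception):
    """Base class for all package errors."""


class ValidationError(LungCTError):
    """An input value violates a documented precondition."""


class ConfigurationError(LungCTError):
    """A configuration block is inconsistent or names an unknown option."""


class DecodeError(LungCTError):
    """An image file could not be read or decoded."""


class StageError(LungCTError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
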