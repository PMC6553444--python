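"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class RgcscanError(Exception):
    """Base class for all package errors."""


class ConfigError(RgcscanError):
    """Invalid configuration or parameters."""


class DataError(RgcscanError):
    """Malformed or inconsistent input data."""


class StageError(RgcscanError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
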