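"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, FormatError -> 3,
StageError -> 4.
"""


class MirdegreeError(Exception):
    """Base class for all package errors."""


class ConfigError(MirdegreeError):
    """Invalid configuration or argument values."""


class FormatError(MirdegreeError):
    """Malformed input file (missing column, bad line, duplicate key)."""


class StageError(MirdegreeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
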