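"""Exception hierarchy shared across the package.

Exit-code mapping for the CLI: ConfigError -> 2, ParseError -> 3,
StageError -> 4.
"""


class LncOraError(Exception):
    """Base class for all package errors."""


class ConfigError(LncOraError):
    """Invalid configuration or parameter combination."""


class ParseError(LncOraError):
    """Malformed input file (GTF, OBO, GAF, TSV)."""


class StageError(LncOraError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
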