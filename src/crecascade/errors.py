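"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataIntegrityError -> 3,
any other StageError -> 4.
"""


class CrecascadeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(CrecascadeError):
    """Invalid configuration value or unknown configuration key."""


class DataIntegrityError(CrecascadeError):
    """Cross-file or cross-table inconsistency (ids, dimensions, coordinates)."""


class ParseError(CrecascadeError):
    """Malformed input file; message carries the offending line number."""


class StageError(CrecascadeError):
    """A pipeline stage failed or was run before its dependencies."""
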