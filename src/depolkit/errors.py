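"""Exception hierarchy shared across the package.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class DepolkitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DepolkitError):
    """Invalid or incomplete run configuration."""


class DataError(DepolkitError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Alignment-level violation (ragged rows, duplicate names, ...)."""


class ParseError(DataError):
    """Low-level parse failure; message names the offending location."""


class TreeError(DataError):
    """Tree structure or branch-length violation."""
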