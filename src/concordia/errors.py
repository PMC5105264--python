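"""Exception hierarchy with stable CLI exit codes.

Exit code map: 0 success, 3 configuration, 4 parse, 5 data, 6 pipeline.
Code 1 is reserved for unexpected failures, 2 for CLI usage errors (click).
"""


class ConcordiaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(ConcordiaError):
    """Invalid configuration or parameter outside its documented range."""

    exit_code = 3


class ParseError(ConcordiaError):
    """Malformed input file content."""

    exit_code = 4


class DataError(ConcordiaError):
    """Structurally valid input that violates a dataset invariant."""

    exit_code = 5


class PipelineError(ConcordiaError):
    """A processing stage produced an empty or unusable result."""

    exit_code = 6
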