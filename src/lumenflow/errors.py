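"""Exception hierarchy mapped onto CLI exit codes."""


class LumenflowError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(LumenflowError):
    """Invalid configuration or parameter combination."""

    exit_code = 2


class DataError(LumenflowError):
    """Malformed, missing, or degenerate input data."""

    exit_code = 3


class TrainingError(LumenflowError):
    """Training diverged or could not proceed."""

    exit_code = 4
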