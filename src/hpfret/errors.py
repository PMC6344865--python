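"""Exception taxonomy shared by the library and the CLI exit codes."""


class HpfretError(Exception):
    """Base class for package errors."""

    exit_code = 1


class ConfigError(HpfretError):
    """Invalid configuration or parameters."""

    exit_code = 2


class DataError(HpfretError):
    """Malformed or unusable input data."""

    exit_code = 3


class NumericalError(HpfretError):
    """A fit or numerical procedure failed to converge."""

    exit_code = 4
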