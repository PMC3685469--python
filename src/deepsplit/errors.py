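"""Exception hierarchy shared across the package."""


class DeepsplitError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(DeepsplitError):
    """Invalid configuration value; the message names the offending field."""


class InputError(DeepsplitError):
    """Malformed or inconsistent user input (sequences, tables, trees)."""


class ParseError(InputError):
    """A file could not be parsed; the message carries the line number."""
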