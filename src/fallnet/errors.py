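"""Exception hierarchy shared across the package."""


class FallnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FallnetError):
    """A file does not match the declared table dialect (e.g. missing column)."""


class DataError(FallnetError):
    """The file parses but violates a data invariant (gaps, bad annotations...)."""


class ConfigError(FallnetError):
    """A configuration object or argument is invalid."""
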