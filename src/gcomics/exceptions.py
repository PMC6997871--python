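"""Package exception hierarchy.

``ConfigurationError`` covers invalid generator / pipeline settings (CLI exit
code 2), ``DataError`` covers malformed or inconsistent inputs (exit code 3).
"""


class GcomicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GcomicsError):
    """Invalid configuration: non-positive counts, bad thresholds, etc."""


class DataError(GcomicsError):
    """Inconsistent or malformed data: duplicate ids, wrong space, etc."""
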