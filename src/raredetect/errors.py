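"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: configuration problems exit 2,
data problems exit 3.
"""


class RareDetectError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RareDetectError):
    """Invalid configuration: bad value set reference, bad rules file, etc."""


class DataError(RareDetectError):
    """Invalid input data: missing file, malformed table, broken invariant."""
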