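"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes (data problems vs numerical
failures), so library code should raise the most specific type that applies.
"""


class EBPRSError(Exception):
    """Base class for all package errors."""


class DataError(EBPRSError):
    """Malformed, inconsistent, or unusable input data."""


class NumericalError(EBPRSError):
    """A numerical routine failed to produce a usable result."""
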