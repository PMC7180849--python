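"""Exception hierarchy.

ValidationError maps to CLI exit code 2 (bad configuration / bad request),
DataError to exit code 3 (the data itself violates a contract).
"""


class OdormapError(Exception):
    """Base class for all package errors."""


class ValidationError(OdormapError):
    """Invalid configuration, parameters, or misuse of an operation."""


class DataError(OdormapError):
    """Input data violates an invariant (duplicates, bad ranges, emptiness)."""
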