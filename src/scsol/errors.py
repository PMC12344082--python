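"""Exception types shared across the package."""


class ScsolError(Exception):
    """Base class for package errors."""


class SchemaError(ScsolError, KeyError):
    """A required column is missing from an input table."""


class ValidationError(ScsolError, ValueError):
    """An input value violates a physical or structural invariant."""


class GridLookupError(ScsolError, LookupError):
    """A (T, P) query falls off the tabulated density grid."""


class ConvergenceError(ScsolError, RuntimeError):
    """An iterative solver or optimiser failed to converge."""


class PairingError(ScsolError, ValueError):
    """Binary/ternary records could not be matched on (T, P)."""


class ConfigError(ScsolError, ValueError):
    """An optimiser or generator configuration is invalid."""
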