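"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class PhoskinError(Exception):
    """Base class for all package errors."""


class ConfigError(PhoskinError):
    """Invalid configuration: bad ranges, unknown keys, inconsistent modes."""


class DataError(PhoskinError):
    """Malformed or insufficient input data."""


class InvalidInputError(DataError, ValueError):
    """A scalar argument violates its precondition (e.g. negative substrate)."""


class InsufficientDesignError(DataError):
    """Too few distinct substrate concentrations to fit a saturation curve."""


class UndefinedCorrectionError(DataError):
    """Plate background OD is not below the sample OD."""


class NumericalError(PhoskinError):
    """A numerical procedure failed."""


class FitFailureError(NumericalError):
    """Nonlinear least squares did not converge or the data are degenerate."""


class IntegrationError(NumericalError):
    """The ODE solver failed; carries solver diagnostics in the message."""


class EnsembleQualityError(NumericalError):
    """Too large a fraction of ensemble draws failed to integrate."""
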