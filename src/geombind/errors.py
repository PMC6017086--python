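"""Exception hierarchy.

Three error families map onto distinct CLI exit codes: configuration
problems (bad input before any computation starts), contract violations
(preconditions of an operation not met by otherwise well-formed data) and
numerical failures (NaN propagation, non-convergence).
"""


class GeombindError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GeombindError):
    """Invalid configuration or input file; raised before any dynamics."""

    exit_code = 2


class ContractError(GeombindError):
    """An operation's precondition was violated by the supplied data."""

    exit_code = 4


class NumericalError(GeombindError):
    """Numerical failure at run time (NaN propagation, divergence)."""

    exit_code = 3
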