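"""Exception hierarchy for cryptdrift."""


class CryptDriftError(Exception):
    """Base class for all cryptdrift errors."""


class InvalidConfigurationError(CryptDriftError, ValueError):
    """A parameter set is structurally invalid (e.g. no displaced stem-cell pool)."""


class NonHomeostaticError(CryptDriftError, ValueError):
    """Raised when a steady state is requested for a tumorigenic parameter set.

    The crypt compartment model only admits a finite steady state when the
    commitment-to-differentiation rate exceeds the stem-cell division rate
    (nu > lambda).  Parameter sets violating this describe exponential growth,
    i.e. tumorigenesis, and are handled by :mod:`cryptdrift.tradeoff` instead.
    """


class TumorigenicRateError(CryptDriftError, ValueError):
    """An expected mutated rate crossed the tumorigenic threshold (lambda >= nu)."""


class GridCoverageError(CryptDriftError, RuntimeError):
    """Probability mass escaped the rate grid, or a threshold lies outside it.

    Rebuild the density grid with a wider span (see ``make_rate_grid``).
    """


class QuadratureError(CryptDriftError, RuntimeError):
    """Numerical quadrature failed to converge; diagnostics in the message."""
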