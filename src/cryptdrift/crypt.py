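"""Deterministic compartment model of a single crypt system.

The time-dependent compartment means obey the linear ODE system

    dx2/dt = lambda*x1 + lambda*x2 - nu*x2
    dy1/dt = nu*x2 - gamma*y1
    dy_{i+1}/dt = 2*gamma*y_i - gamma*y_{i+1}      (i = 1..R-1)
    dz/dt  = 2*gamma*y_R - delta*z

with the niche census x1 held fixed.  Setting the derivatives to zero gives
the closed-form steady state; in particular the postmitotic pool mean is

    Z* = 2**R * nu * lambda * X1 / (delta * (nu - lambda)),

finite only on the homeostatic region nu > lambda.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import InvalidConfigurationError, NonHomeostaticError, QuadratureError
from .params import CryptParameters

__all__ = [
    "CryptSteadyState",
    "commitment_rate",
    "steady_state",
    "integrate_means",
    "population_ratio",
    "population_ratio_differentiation",
]

# Internal consistency requirement between the two closed-form routes to Z*.
_Z_CONSISTENCY_RTOL = 1e-12


@dataclass(frozen=True)
class CryptSteadyState:
    """Steady-state compartment means of one crypt.

    Attributes
    ----------
    displaced : float
        Displaced stem-cell pool mean, X2* = lambda*X1/(nu - lambda).
    ta_pools : tuple of float
        The R transit-amplifying pool means; each doubles the previous.
    postmitotic : float
        Terminally differentiated pool mean Z*.
    """

    displaced: float
    ta_pools: tuple
    postmitotic: float

    @property
    def ta_total(self) -> float:
        """Total transit-amplifying population."""
        return float(sum(self.ta_pools))

    def as_series(self) -> pd.Series:
        """Pool means keyed by pool name (x2, y1..yR, z)."""
        data = {"x2": self.displaced}
        data.update({f"y{i + 1}": y for i, y in enumerate(self.ta_pools)})
        data["z"] = self.postmitotic
        return pd.Series(data, name="mean_cells")


def commitment_rate(division_rate: float, niche_size: int, total_stem: float) -> float:
    """Commitment-to-differentiation rate holding the total stem pool steady.

    Given the niche census ``niche_size`` (X1), the symmetric division rate
    (lambda) and a target total stem-cell population X1 + X2, the displaced
    pool is steady when ``lambda*X1 + lambda*X2 = nu*X2``, i.e.

        nu = lambda * total_stem / (total_stem - niche_size).

    The returned rate always exceeds ``division_rate``, so the derived crypt
    is homeostatic by construction.

    Examples
    --------
    >>> round(commitment_rate(0.2, 6, 15), 3)   # mouse small intestine
    0.333
    """
    if division_rate <= 0:
        raise InvalidConfigurationError("division_rate must be strictly positive")
    if niche_size < 1:
        raise InvalidConfigurationError("niche_size must be >= 1")
    if total_stem <= niche_size:
        raise InvalidConfigurationError(
            f"total_stem ({total_stem}) must exceed niche_size ({niche_size}): "
            "otherwise there is no displaced stem-cell pool to absorb niche output"
        )
    return division_rate * total_stem / (total_stem - niche_size)


def steady_state(params: CryptParameters) -> CryptSteadyState:
    """Closed-form steady state of the crypt compartment model.

    Raises
    ------
    NonHomeostaticError
        If ``nu <= lambda`` — a tumorigenic parameter set with no finite
        steady state.
    """
    lam = params.division_rate
    nu = params.differentiation_rate
    if not params.is_homeostatic:
        raise NonHomeostaticError(
            f"no steady state: differentiation rate nu={nu} must exceed "
            f"division rate lambda={lam} (tumorigenic configuration)"
        )
    x2 = lam * params.niche_size / (nu - lam)
    y1 = nu * x2 / params.ta_division_rate
    ta = tuple(y1 * 2.0**i for i in range(params.ta_rounds))
    # Closed form for Z*; cross-checked against the flux balance 2*gamma*Y_R/delta.
    z_closed = (
        2.0**params.ta_rounds * nu * lam * params.niche_size
        / (params.death_rate * (nu - lam))
    )
    z_flux = 2.0 * params.ta_division_rate * ta[-1] / params.death_rate
    if abs(z_closed - z_flux) > _Z_CONSISTENCY_RTOL * abs(z_closed):
        raise QuadratureError(
            f"steady-state routes disagree: closed form {z_closed!r} vs flux {z_flux!r}"
        )
    return CryptSteadyState(displaced=x2, ta_pools=ta, postmitotic=z_closed)


def _rhs(params: CryptParameters):
    lam = params.division_rate
    nu = params.differentiation_rate
    gam = params.ta_division_rate
    delta = params.death_rate
    R = params.ta_rounds
    x1 = params.niche_size

    def f(_t: float, y: np.ndarray) -> np.ndarray:
        # y = [x2, y1..yR, z]
        dy = np.empty_like(y)
        dy[0] = lam * x1 + lam * y[0] - nu * y[0]
        dy[1] = nu * y[0] - gam * y[1]
        for i in range(2, R + 1):
            dy[i] = 2.0 * gam * y[i - 1] - gam * y[i]
        dy[R + 1] = 2.0 * gam * y[R] - delta * y[R + 1]
        return dy

    return f


def integrate_means(
    params: CryptParameters,
    init: Sequence[float],
    t_grid: Sequence[float],
    rtol: float = 1e-9,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Numerically integrate the compartment-mean ODE system.

    Parameters
    ----------
    params : CryptParameters
        Crypt rate constants.  Homeostasis is *not* required: the transient
        dynamics are well defined for any rates.
    init : sequence of float
        Initial pool means ``[x2, y1, ..., yR, z]`` (length R + 2),
        non-negative.
    t_grid : sequence of float
        Strictly increasing evaluation times in days.

    Returns
    -------
    pandas.DataFrame
        One row per time point; columns ``t_days, x2, y1..yR, z``.

    Notes
    -----
    Uses a stiff-capable integrator (LSODA) because the TA division rate is an
    order of magnitude faster than the stem-cell rates, giving moderate scale
    separation.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 1 or np.any(np.diff(t) <= 0):
        raise InvalidConfigurationError("t_grid must be strictly increasing")
    y0 = np.asarray(init, dtype=float)
    if len(y0) != params.ta_rounds + 2:
        raise InvalidConfigurationError(
            f"init must have length R + 2 = {params.ta_rounds + 2}, got {len(y0)}"
        )
    if np.any(y0 < 0):
        raise InvalidConfigurationError("initial pool means must be non-negative")

    t0 = min(0.0, t[0])
    sol = solve_ivp(
        _rhs(params), (t0, t[-1]), y0, t_eval=t, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise QuadratureError(f"ODE solver failed: {sol.message}")
    cols = ["x2"] + [f"y{i + 1}" for i in range(params.ta_rounds)] + ["z"]
    out = pd.DataFrame(sol.y.T, columns=cols)
    out.insert(0, "t_days", sol.t)
    return out


def population_ratio(lam0: float, lam1: float, nu: float) -> float:
    """Postmitotic steady-state ratio Z1*/Z0* after a division-rate change.

    All crypt parameters other than the division rate cancel, leaving

        Z1*/Z0* = (lam1/lam0) * (nu - lam0) / (nu - lam1).

    A small proportional change in lambda is amplified in the postmitotic
    population because the denominator nu - lambda shrinks as lambda rises.
    """
    if nu <= lam0:
        raise NonHomeostaticError("baseline configuration is not homeostatic (nu <= lam0)")
    if nu <= lam1:
        raise NonHomeostaticError(
            "mutated configuration is tumorigenic (nu <= lam1): ratio undefined"
        )
    return (lam1 / lam0) * (nu - lam0) / (nu - lam1)


def population_ratio_differentiation(nu0: float, nu1: float, lam: float) -> float:
    """Postmitotic steady-state ratio Z1*/Z0* after a differentiation-rate change.

        Z1*/Z0* = (nu1/nu0) * (nu0 - lam) / (nu1 - lam).
    """
    if nu0 <= lam:
        raise NonHomeostaticError("baseline configuration is not homeostatic (nu0 <= lam)")
    if nu1 <= lam:
        raise NonHomeostaticError(
            "mutated configuration is tumorigenic (nu1 <= lam): ratio undefined"
        )
    return (nu1 / nu0) * (nu0 - lam) / (nu1 - lam)
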