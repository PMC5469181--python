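"""Mutation fixation machinery for stem-cell niches.

This module implements the evolutionary core of the package:

* the mirrored-exponential distribution of fitness effects (DFE) acting
  multiplicatively on a stem-cell rate,
* the ring-Moran fixation probability of a mutant lineage in a niche of X1
  cells, ``pfix(r) = (1 - 1/r) / (1 - r**-X1)``,
* the posterior density of the rate given that a mutant lineage fixed
  (Bayes' rule: prior DFE weighted by fixation probability),
* the recursion propagating that posterior over successive fixations, and
* the parameter-space boundary separating net-beneficial from net-deleterious
  expected accumulation.

Mutations to the division rate feel selection inside the niche (faster
dividers displace neighbours more often); mutations to the differentiation
rate are invisible to niche competition and fix neutrally with probability
1/X1, so their posterior equals the prior DFE.

All densities are discretized on a fixed rate grid and integrated by the
trapezoid rule; the grid spans enough exponential e-folds that truncated tail
mass is negligible (checked at every step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import GridCoverageError, InvalidConfigurationError
from .params import DFEParameters, _check_target

__all__ = [
    "RateDensity",
    "FixationSummary",
    "FixationKernel",
    "dfe_density",
    "fixation_probability",
    "make_rate_grid",
    "posterior_fixed_density",
    "iterate_density",
    "density_sequence",
    "expected_effect_boundary",
]

# Grid span in e-folds of the relevant exponential tail.  20 e-folds leave
# ~1e-9 relative tail mass, comfortably under the escape tolerance below.
_SPAN_EFOLDS = 20.0
_ESCAPE_TOL = 1e-6
_NORMALIZATION_TOL = 1e-6
_DEFAULT_N_GRID = 2**13


@dataclass
class RateDensity:
    """Discretized probability density of a stem-cell rate after m fixations.

    ``m = 0`` is the analytic point mass at the baseline rate ``r0`` and is
    flagged by ``point_mass``; its ``grid``/``density`` are empty.
    """

    target: str
    r0: float
    grid: np.ndarray
    density: np.ndarray
    m: int
    point_mass: bool = False

    @classmethod
    def initial(cls, r0: float, target: str) -> "RateDensity":
        """The m = 0 point mass at the unmutated baseline rate."""
        _check_target(target)
        return cls(
            target=target, r0=float(r0),
            grid=np.empty(0), density=np.empty(0), m=0, point_mass=True,
        )

    def mass(self) -> float:
        """Trapezoid integral of the density over the grid."""
        if self.point_mass:
            return 1.0
        return float(np.trapezoid(self.density, self.grid))

    def mean(self) -> float:
        """Expected rate, integral of rate times density."""
        if self.point_mass:
            return self.r0
        return float(np.trapezoid(self.grid * self.density, self.grid))

    def expected_ratio(self) -> float:
        """Expected rate divided by the baseline rate."""
        return self.mean() / self.r0

    def mass_above(self, threshold: float) -> float:
        """Probability mass at rates strictly above ``threshold``."""
        return self._partial_mass(threshold, upper=True)

    def mass_below(self, threshold: float) -> float:
        """Probability mass at rates below ``threshold``."""
        return self._partial_mass(threshold, upper=False)

    def _partial_mass(self, threshold: float, upper: bool) -> float:
        if self.point_mass:
            if upper:
                return 1.0 if self.r0 > threshold else 0.0
            return 1.0 if self.r0 < threshold else 0.0
        g, d = self.grid, self.density
        if threshold <= g[0]:
            return self.mass() if upper else 0.0
        if threshold >= g[-1]:
            if upper:
                raise GridCoverageError(
                    f"threshold {threshold} is at or beyond the grid end {g[-1]}: "
                    "rebuild the density grid with cover_threshold set"
                )
            return self.mass()
        # Split the straddling trapezoid cell at the threshold.
        d_at = float(np.interp(threshold, g, d))
        i = int(np.searchsorted(g, threshold))
        below = np.trapezoid(d[:i], g[:i]) + 0.5 * (d[i - 1] + d_at) * (threshold - g[i - 1])
        return self.mass() - below if upper else float(below)


@dataclass(frozen=True)
class FixationSummary:
    """Headline quantities of the first-fixation posterior.

    Attributes
    ----------
    p_hat : float
        Total fixation probability of a new fitness-affecting mutant,
        integral of pfix against the DFE.
    expected_ratio : float
        Expected rate after one fixed mutation divided by the baseline rate
        (r_lambda for division, r_nu for differentiation).
    mu_hat : float or None
        Arrival rate of fixed lineages per crypt per day,
        ``p_hat * mu * lambda0 * X1``; None when the niche division rate was
        not supplied.
    """

    p_hat: float
    expected_ratio: float
    mu_hat: Optional[float] = None


# ---------------------------------------------------------------------------
# DFE density
# ---------------------------------------------------------------------------

def dfe_density(
    rate,
    r0: float,
    dfe: DFEParameters,
    target: str = "division",
    renormalize: bool = True,
):
    """Mirrored-exponential DFE density of the mutated rate.

    For division-rate mutations the deleterious branch sits below the
    baseline ``r0`` (weight ``1 - P_B``, exponential shape ``beta``) and the
    beneficial branch above it (weight ``P_B``, shape ``alpha``).  For
    differentiation-rate mutations the branches are mirrored: beneficial
    mutations *decrease* nu (longer-lived lineage contribution), deleterious
    mutations increase it.

    The branch whose support is truncated at rate 0 (deleterious for
    division, beneficial for differentiation) loses tail mass ``e**-shape``
    below zero; with ``renormalize`` (default) that branch is rescaled so the
    branch weights remain exactly ``1 - P_B`` and ``P_B``.

    Parameters are vectorized over ``rate``.
    """
    _check_target(target)
    if r0 <= 0:
        raise InvalidConfigurationError("baseline rate r0 must be strictly positive")
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise InvalidConfigurationError("rates must be non-negative")
    x = rate / r0
    pb = dfe.beneficial_fraction
    alpha, beta = dfe.alpha, dfe.beta

    if target == "division":
        below = (1.0 - pb) * beta * np.exp(-beta * (1.0 - x))
        if renormalize:
            below = below / -np.expm1(-beta)
        above = pb * alpha * np.exp(-alpha * (x - 1.0))
    else:
        below = pb * alpha * np.exp(-alpha * (1.0 - x))
        if renormalize:
            below = below / -np.expm1(-alpha)
        above = (1.0 - pb) * beta * np.exp(-beta * (x - 1.0))

    out = np.where(x < 1.0, below, above)
    # At the jump itself use the mean of the one-sided limits: the trapezoid
    # errors of the two adjacent cells then cancel to second order.
    out = np.where(x == 1.0, 0.5 * (below + above), out) / r0
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Fixation probability
# ---------------------------------------------------------------------------

def fixation_probability(r, niche_size: int):
    """Fixation probability of a mutant lineage on a ring of X1 stem cells.

    ``pfix(r) = (1 - r**-1) / (1 - r**-X1)`` where r is the mutant division
    rate relative to the resident rate.  Continuous at r = 1 with the neutral
    value 1/X1; equal to 1 for a single-cell niche.  Evaluated via
    ``expm1(-u)/expm1(-X1*u)`` with ``u = log r``, which is stable through
    the neutral point.

    Vectorized over ``r``.
    """
    if niche_size < 1:
        raise InvalidConfigurationError("niche_size must be >= 1")
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise InvalidConfigurationError("relative rate r must be strictly positive")
    if niche_size == 1:
        out = np.ones_like(r)
        return out if out.ndim else 1.0
    u = np.log(r)
    with np.errstate(over="ignore", invalid="ignore"):
        num = np.expm1(-u)
        den = np.expm1(-niche_size * u)
        out = np.where(u == 0.0, 1.0 / niche_size, num / den)
        # Deep-deleterious overflow: both expm1 terms blow up, limit is 0.
        out = np.where(np.isinf(den), np.where(np.isinf(num), 0.0, 0.0), out)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Grids
# ---------------------------------------------------------------------------

def make_rate_grid(
    r0: float,
    dfe: DFEParameters,
    target: str = "division",
    m_span: int = 1,
    n_grid: int = _DEFAULT_N_GRID,
    cover_threshold: Optional[float] = None,
) -> np.ndarray:
    """Linear rate grid wide enough for ``m_span`` successive fixations.

    Division-rate densities drift downward and are naturally truncated at 0;
    the upper bound leaves ``_SPAN_EFOLDS`` e-folds of the beneficial tail per
    fixation.  Differentiation densities drift upward with the wider
    deleterious scale.  ``cover_threshold`` extends the grid so one-sided
    exceedance masses at a tumorigenic threshold are resolved.  The baseline
    rate ``r0`` is always a grid node (the density has a kink there).
    """
    _check_target(target)
    if r0 <= 0:
        raise InvalidConfigurationError("r0 must be strictly positive")
    m_span = max(1, int(m_span))
    sp = dfe.mean_beneficial_effect
    sm = dfe.mean_deleterious_effect
    if target == "division":
        lo = 0.0
        hi = r0 * (1.0 + _SPAN_EFOLDS * sp * m_span)
    else:
        lo = max(0.0, r0 * (1.0 - _SPAN_EFOLDS * sp * m_span))
        hi = r0 * (1.0 + _SPAN_EFOLDS * sm * m_span)
    if cover_threshold is not None and cover_threshold > 0:
        if target == "division":
            hi = max(hi, cover_threshold * (1.0 + _SPAN_EFOLDS * sp))
        else:
            lo = min(lo, max(0.0, cover_threshold * (1.0 - _SPAN_EFOLDS * sp)))
    # Two linear segments meeting exactly at r0.
    n_lo = max(8, int(round(n_grid * (r0 - lo) / (hi - lo))))
    n_lo = min(n_lo, n_grid - 8)
    left = np.linspace(lo, r0, n_lo, endpoint=False)
    right = np.linspace(r0, hi, n_grid - n_lo)
    return np.concatenate([left, right])


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    d = np.diff(grid)
    w[0] = d[0] / 2.0
    w[-1] = d[-1] / 2.0
    w[1:-1] = (d[:-1] + d[1:]) / 2.0
    return w


# ---------------------------------------------------------------------------
# Posterior after one fixation
# ---------------------------------------------------------------------------

def posterior_fixed_density(
    r0: float,
    niche_size: int,
    dfe: DFEParameters,
    target: str = "division",
    grid: Optional[np.ndarray] = None,
    n_grid: int = _DEFAULT_N_GRID,
    division_rate: Optional[float] = None,
    renormalize: bool = True,
):
    """Density of the stem-cell rate given that one mutant lineage fixed.

    Bayes' rule: the prior DFE is weighted by the fixation probability and
    normalized; the normalizing constant is the total fixation probability
    ``p_hat``.  For differentiation-rate mutations the weight is the constant
    neutral probability 1/X1, which cancels, so the posterior equals the
    prior and is independent of niche size.

    Parameters
    ----------
    division_rate : float, optional
        Niche division rate lambda0 used for the fixed-lineage arrival rate
        ``mu_hat = p_hat * mu * lambda0 * X1``.  Defaults to ``r0`` for the
        division target (where the two coincide).

    Returns
    -------
    (RateDensity, FixationSummary)
    """
    _check_target(target)
    if grid is None:
        grid = make_rate_grid(r0, dfe, target, m_span=1, n_grid=n_grid)
    prior = dfe_density(grid, r0, dfe, target, renormalize=renormalize)
    if target == "division":
        weight = np.zeros_like(grid)
        pos = grid > 0
        weight[pos] = fixation_probability(grid[pos] / r0, niche_size)
        if niche_size == 1:
            weight[~pos] = 1.0  # single lineage: arrival is fixation
        integrand = prior * weight
        p_hat = float(np.trapezoid(integrand, grid))
        if p_hat <= 0:
            raise GridCoverageError(
                "posterior normalization vanished; grid does not cover the DFE"
            )
        density = integrand / p_hat
    else:
        # Neutral fixation: the constant 1/X1 weight cancels in the posterior,
        # which therefore equals the prior, independent of niche size.
        mass = float(np.trapezoid(prior, grid))
        if mass <= 0:
            raise GridCoverageError(
                "posterior normalization vanished; grid does not cover the DFE"
            )
        p_hat = mass / niche_size
        density = prior / mass
    dens = RateDensity(target=target, r0=float(r0), grid=grid, density=density, m=1)
    expected_ratio = dens.expected_ratio()
    mu_hat = None
    lam0 = division_rate if division_rate is not None else (r0 if target == "division" else None)
    if lam0 is not None:
        mu_hat = p_hat * dfe.mutation_rate * lam0 * niche_size
    return dens, FixationSummary(p_hat=p_hat, expected_ratio=expected_ratio, mu_hat=mu_hat)


# ---------------------------------------------------------------------------
# Recursion over successive fixations
# ---------------------------------------------------------------------------

class FixationKernel:
    """Dense Markov kernel propagating the rate density across one fixation.

    Entry (i, j) discretizes the posterior density of the new rate
    ``grid[i]`` given the pre-fixation baseline ``grid[j]``.  Columns are
    normalized on the grid, so propagation conserves probability mass by
    construction; a boundary-mass guard detects densities drifting off the
    grid.  Built once per (grid, niche size, DFE, target) and reused — the
    recursion rarely needs more than a few tens of iterations.
    """

    def __init__(
        self,
        grid: np.ndarray,
        niche_size: int,
        dfe: DFEParameters,
        target: str = "division",
        renormalize: bool = True,
        chunk: int = 1024,
    ) -> None:
        _check_target(target)
        self.grid = np.asarray(grid, dtype=float)
        self.niche_size = int(niche_size)
        self.dfe = dfe
        self.target = target
        n = len(self.grid)
        self.weights = _trapezoid_weights(self.grid)
        K = np.empty((n, n))
        x = self.grid[:, None]
        tiny = max(self.grid[-1], 1.0) * 1e-12
        for j0 in range(0, n, chunk):
            j1 = min(j0 + chunk, n)
            ell = self.grid[None, j0:j1]
            safe = np.maximum(ell, tiny)
            xr = x / safe
            pb = dfe.beneficial_fraction
            alpha, beta = dfe.alpha, dfe.beta
            # Exponent arguments are clamped at 0: each branch is only used
            # on its own side of xr = 1, where its argument is negative.
            if target == "division":
                below = (1.0 - pb) * beta * np.exp(np.minimum(-beta * (1.0 - xr), 0.0))
                if renormalize:
                    below = below / -np.expm1(-beta)
                above = pb * alpha * np.exp(np.minimum(-alpha * (xr - 1.0), 0.0))
            else:
                below = pb * alpha * np.exp(np.minimum(-alpha * (1.0 - xr), 0.0))
                if renormalize:
                    below = below / -np.expm1(-alpha)
                above = (1.0 - pb) * beta * np.exp(np.minimum(-beta * (xr - 1.0), 0.0))
            dens = np.where(xr < 1.0, below, above)
            # Mean of the one-sided limits at the kink (see dfe_density).
            dens = np.where(xr == 1.0, 0.5 * (below + above), dens) / safe
            if target == "division" and niche_size > 1:
                with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                    u = np.log(np.maximum(xr, 1e-300))
                    num = np.expm1(-u)
                    den = np.expm1(-niche_size * u)
                    w = np.where(u == 0.0, 1.0 / niche_size, num / den)
                    w = np.where(np.isfinite(w), w, 0.0)
                dens = dens * w
            K[:, j0:j1] = dens
        # Degenerate columns (baseline at/near rate zero): absorbing state.
        col_mass = self.weights @ K
        dead = (self.grid <= tiny) | (col_mass <= 0)
        for j in np.flatnonzero(dead):
            K[:, j] = 0.0
            K[j, j] = 1.0 / max(self.weights[j], 1e-300)
            col_mass[j] = 1.0
        K /= col_mass[None, :]
        self.matrix = K

    def propagate(self, f: RateDensity) -> RateDensity:
        """Apply the kernel once: density after m fixations -> after m + 1."""
        if f.point_mass:
            dens, _ = posterior_fixed_density(
                f.r0, self.niche_size, self.dfe, self.target, grid=self.grid
            )
            dens.m = f.m + 1
            return dens
        if f.grid.shape != self.grid.shape or not np.allclose(f.grid, self.grid):
            raise GridCoverageError("density grid does not match the kernel grid")
        new = self.matrix @ (self.weights * f.density)
        out = RateDensity(
            target=f.target, r0=f.r0, grid=self.grid, density=new, m=f.m + 1
        )
        self._check_containment(out)
        mass = out.mass()
        if abs(mass - 1.0) > _NORMALIZATION_TOL:
            raise GridCoverageError(
                f"kernel iteration lost probability mass (mass = {mass}); extend the grid"
            )
        out.density = out.density / mass
        return out

    def _check_containment(self, f: RateDensity) -> None:
        # Mass piled into the outer 1% of the grid signals imminent escape.
        n_edge = max(2, len(self.grid) // 100)
        top = np.trapezoid(f.density[-n_edge:], f.grid[-n_edge:])
        if top > _ESCAPE_TOL:
            raise GridCoverageError(
                f"density mass {top:.2e} near the grid upper edge exceeds "
                f"{_ESCAPE_TOL}: rebuild the grid with a larger m_span"
            )


def iterate_density(
    f_n: RateDensity,
    niche_size: int,
    dfe: DFEParameters,
    kernel: Optional[FixationKernel] = None,
) -> RateDensity:
    """One step of the fixation recursion, f_m -> f_{m+1}.

    Builds a :class:`FixationKernel` on ``f_n``'s grid if none is supplied;
    pass a prebuilt kernel when iterating many times.
    """
    if kernel is None:
        grid = f_n.grid if not f_n.point_mass else make_rate_grid(
            f_n.r0, dfe, f_n.target, m_span=max(2, f_n.m + 1)
        )
        kernel = FixationKernel(grid, niche_size, dfe, f_n.target)
    return kernel.propagate(f_n)


def density_sequence(
    r0: float,
    niche_size: int,
    dfe: DFEParameters,
    target: str = "division",
    m_max: int = 10,
    n_grid: int = _DEFAULT_N_GRID,
    cover_threshold: Optional[float] = None,
    division_rate: Optional[float] = None,
):
    """Densities after 1..m_max fixations, plus the first-fixation summary.

    Convenience pipeline: builds one grid sized for ``m_max`` fixations (and
    optionally covering a tumorigenic threshold), the kernel, and the full
    sequence of propagated densities.

    Returns
    -------
    (list of RateDensity, FixationSummary, FixationKernel)
    """
    grid = make_rate_grid(
        r0, dfe, target, m_span=m_max, n_grid=n_grid, cover_threshold=cover_threshold
    )
    f1, summary = posterior_fixed_density(
        r0, niche_size, dfe, target, grid=grid, division_rate=division_rate
    )
    if m_max < 1:
        return [], summary, None
    kernel = FixationKernel(grid, niche_size, dfe, target)
    densities = [f1]
    for _ in range(1, m_max):
        densities.append(kernel.propagate(densities[-1]))
    return densities, summary, kernel


# ---------------------------------------------------------------------------
# Expected-effect boundary in DFE parameter space
# ---------------------------------------------------------------------------

def _expected_ratio(niche_size, s_minus, s_plus, p_b, n_grid):
    dfe = DFEParameters(
        mutation_rate=1e-4,  # irrelevant to the ratio
        mean_deleterious_effect=s_minus,
        mean_beneficial_effect=s_plus,
        beneficial_fraction=p_b,
    )
    _, summary = posterior_fixed_density(1.0, niche_size, dfe, "division", n_grid=n_grid)
    return summary.expected_ratio

def expected_effect_boundary(
    niche_size: int,
    s_plus: float,
    p_b_values: Sequence[float],
    s_minus_range=(1e-3, 2.0),
    n_grid: int = 2**11,
    xtol: float = 1e-8,
) -> np.ndarray:
    """Deleterious scale at which fixed division-rate mutations break even.

    For each beneficial fraction in ``p_b_values``, finds the smallest
    ``s_minus`` in ``s_minus_range`` where the expected post-fixation rate
    ratio equals 1, separating parameter regions where fixed mutations are
    expected to be net beneficial (ratio > 1) from net deleterious.  Returns
    NaN where the ratio does not cross 1 in the range (uniformly beneficial
    or deleterious).
    """
    out = np.empty(len(p_b_values))
    scan = np.linspace(s_minus_range[0], s_minus_range[1], 33)
    for k, p_b in enumerate(p_b_values):
        g = np.array([
            _expected_ratio(niche_size, s, s_plus, p_b, n_grid) - 1.0 for s in scan
        ])
        sign_change = np.flatnonzero(np.sign(g[:-1]) * np.sign(g[1:]) < 0)
        if len(sign_change) == 0:
            warnings.warn(
                f"expected effect is always {'beneficial' if g[0] > 0 else 'deleterious'} "
                f"for P_B={p_b} over s_minus in {s_minus_range}",
                stacklevel=2,
            )
            out[k] = np.nan
            continue
        i = sign_change[0]
        out[k] = brentq(
            lambda s: _expected_ratio(niche_size, s, s_plus, p_b, n_grid) - 1.0,
            scan[i], scan[i + 1], xtol=xtol,
        )
    return out
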