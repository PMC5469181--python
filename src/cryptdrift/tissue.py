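"""Organism-scale mutation accumulation and epithelial attrition.

Fixed mutations arrive in each crypt as a Poisson process with rate
``mu_hat = p_hat * mu * lambda0 * X1`` (mutant supply times total fixation
probability), so at age t the number of fixed mutations per crypt is
Poisson(mu_hat * t).  Plugging the expected stem-cell rate after m fixations
into the crypt steady state gives the expected whole-epithelium postmitotic
population

    Z*(t) = Z_total* - sum_m n_m(t) * (Z_normal* - Z_m*),

reported as the fraction Z*(t)/Z_total* (the crypt count cancels).  A
first-order expansion in the first fixed mutation yields the linear
attrition slopes

    division:        d/dt (Z*/Z_total*) = -theta*lambda0*mu*p_hat*X1*(r-1)/(r-theta)
    differentiation: d/dt (Z*/Z_total*) = -mu*lambda0*(r-1)/(theta*r-1)

with theta = nu/lambda0 and r the expected post-fixation rate ratio.  The
differentiation slope contains neither X1 nor p_hat: mutations fix neutrally
with probability 1/X1 while each niche supplies mutants at rate
proportional to X1, and the two cancel.  Because the slopes are free of the
TA and postmitotic kinetics — unmeasured in humans — the human scenarios are
computed from them directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats

from .crypt import steady_state
from .dfe import FixationSummary, RateDensity, posterior_fixed_density
from .errors import InvalidConfigurationError, TumorigenicRateError
from .params import CryptParameters, DFEParameters, _check_target
from .presets import HUMAN_COLON_NICHE6, HUMAN_COLON_NICHE20, ScenarioPreset

__all__ = [
    "TissueScenario",
    "AttritionCurve",
    "poisson_mutation_cap",
    "mutation_count_distribution",
    "tissue_trajectory",
    "linear_slope",
    "human_scenarios",
]

_POISSON_TAIL_TOL = 1e-10


@dataclass(frozen=True)
class TissueScenario:
    """A whole-tissue configuration for attrition and tumour-risk pipelines."""

    crypt: CryptParameters
    dfe: DFEParameters
    target: str
    lifetime_days: float
    n_crypts: float = 1.0
    m_cap: Optional[int] = None

    def __post_init__(self) -> None:
        _check_target(self.target)
        if self.lifetime_days <= 0:
            raise InvalidConfigurationError("lifetime_days must be strictly positive")
        if self.n_crypts <= 0:
            raise InvalidConfigurationError("n_crypts must be strictly positive")

    @property
    def baseline_rate(self) -> float:
        """The rate the mutations act on: lambda0 or nu0."""
        if self.target == "division":
            return self.crypt.division_rate
        return self.crypt.differentiation_rate

    @classmethod
    def from_preset(cls, preset: ScenarioPreset, target: str) -> "TissueScenario":
        return cls(
            crypt=preset.crypt,
            dfe=preset.dfe,
            target=target,
            lifetime_days=preset.lifetime_days,
            n_crypts=preset.crypt_count,
        )


@dataclass
class AttritionCurve:
    """Fractional postmitotic tissue size over time.

    ``fraction[i]`` is Z*(times[i]) / Z_total*; ``slope_linear`` is the
    first-order attrition slope per day.
    """

    times: np.ndarray
    fraction: np.ndarray
    slope_linear: float

    def fraction_at_end(self) -> float:
        return float(self.fraction[-1])


def poisson_mutation_cap(mu_hat: float, t: float, tail_tol: float = _POISSON_TAIL_TOL) -> int:
    """Smallest m with Poisson(mu_hat*t) upper-tail mass below ``tail_tol``."""
    if mu_hat < 0 or t < 0:
        raise InvalidConfigurationError("mu_hat and t must be non-negative")
    mean = mu_hat * t
    if mean == 0:
        return 0
    m = int(stats.poisson.isf(tail_tol, mean))
    while stats.poisson.sf(m, mean) >= tail_tol:
        m += 1
    return m


def mutation_count_distribution(
    mu_hat: float,
    t: float,
    n_crypts: float,
    m_cap: Optional[int] = None,
    tail_tol: float = _POISSON_TAIL_TOL,
    check_tail: bool = True,
) -> np.ndarray:
    """Expected number of crypts carrying m fixed mutations, m = 0..m_cap.

    ``n_m = C * exp(-mu_hat*t) * (mu_hat*t)**m / m!``.  The returned counts
    sum to the total crypt count C up to the requested Poisson tail; with
    ``check_tail`` an explicit ``m_cap`` that truncates more than that is
    rejected.
    """
    if mu_hat < 0 or t < 0:
        raise InvalidConfigurationError("mu_hat and t must be non-negative")
    if m_cap is None:
        m_cap = poisson_mutation_cap(mu_hat, t, tail_tol)
    mean = mu_hat * t
    m = np.arange(m_cap + 1)
    pmf = stats.poisson.pmf(m, mean)
    if check_tail and pmf.sum() < 1.0 - max(tail_tol, 1e-8):
        raise InvalidConfigurationError(
            f"m_cap={m_cap} truncates Poisson({mean}) to mass {pmf.sum():.12f}; "
            "increase m_cap"
        )
    return n_crypts * pmf


def _mutated_steady_postmitotic(crypt: CryptParameters, target: str, rate: float) -> float:
    """Z* of a crypt whose targeted stem-cell rate moved to ``rate``."""
    if target == "division":
        if rate >= crypt.differentiation_rate:
            raise TumorigenicRateError(
                f"expected division rate {rate} reached the differentiation rate "
                f"{crypt.differentiation_rate}: the steady state diverges; "
                "use cryptdrift.tradeoff for threshold-crossing probabilities"
            )
        mutated = crypt.with_division_rate(rate)
    else:
        if rate <= crypt.division_rate:
            raise TumorigenicRateError(
                f"expected differentiation rate {rate} fell to the division rate "
                f"{crypt.division_rate}: the steady state diverges; "
                "use cryptdrift.tradeoff for threshold-crossing probabilities"
            )
        mutated = crypt.with_differentiation_rate(rate)
    return steady_state(mutated).postmitotic


def _expectation_mode_z(
    crypt: CryptParameters, target: str, f: RateDensity, margin: float = 1e-3
) -> float:
    """E[Z*(rate)] over f, conditioned on the homeostatic region.

    Z* diverges as the rate approaches the tumorigenic threshold, so the
    expectation is taken conditional on staying a relative ``margin`` away
    from it; any excluded mass is reported as a warning.
    """
    g, d = f.grid, f.density
    if target == "division":
        lim = crypt.differentiation_rate * (1.0 - margin)
        ok = (g < lim) & (g > 0)
        z = np.zeros_like(g)
        z[ok] = [
            steady_state(crypt.with_division_rate(r)).postmitotic for r in g[ok]
        ]
    else:
        lim = crypt.division_rate * (1.0 + margin)
        ok = g > lim
        z = np.zeros_like(g)
        z[ok] = [
            steady_state(crypt.with_differentiation_rate(r)).postmitotic for r in g[ok]
        ]
    kept = np.trapezoid(np.where(ok, d, 0.0), g)
    if kept <= 0:
        raise TumorigenicRateError("all density mass lies in the tumorigenic region")
    excluded = f.mass() - kept
    if excluded > 1e-6:
        warnings.warn(
            f"expectation-mode Z* excludes {excluded:.2e} probability mass within "
            f"{margin:.0e} of the tumorigenic threshold",
            stacklevel=3,
        )
    return float(np.trapezoid(np.where(ok, d, 0.0) * z, g) / kept)


def tissue_trajectory(
    scn: TissueScenario,
    densities: Sequence[RateDensity],
    t_grid: Sequence[float],
    summary: Optional[FixationSummary] = None,
    z_expectation_mode: bool = False,
) -> AttritionCurve:
    """Expected fractional postmitotic tissue size over time.

    Parameters
    ----------
    densities : sequence of RateDensity
        Rate densities after m = 1..m_cap fixations (from
        :func:`cryptdrift.dfe.density_sequence`); must be deep enough to
        cover the Poisson mass at the last time point.
    summary : FixationSummary, optional
        First-fixation summary; recomputed by quadrature when omitted.
    z_expectation_mode : bool
        Default (False) plugs the *expected* mutated rate into the crypt
        steady state.  True instead averages Z* over the rate density,
        conditioning away the divergent tumorigenic region (Jensen-gap
        variant; see docs).
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise InvalidConfigurationError("t_grid must be non-negative and increasing")
    if summary is None:
        _, summary = posterior_fixed_density(
            scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
            division_rate=scn.crypt.division_rate,
        )
    mu_hat = summary.p_hat * scn.dfe.mutation_rate * scn.crypt.division_rate * scn.crypt.niche_size
    m_cap = poisson_mutation_cap(mu_hat, float(t[-1]))
    if scn.m_cap is not None:
        if scn.m_cap < m_cap:
            raise InvalidConfigurationError(
                f"scenario m_cap={scn.m_cap} below required Poisson cap {m_cap}"
            )
        m_cap = min(scn.m_cap, len(densities))
    if len(densities) < m_cap:
        raise InvalidConfigurationError(
            f"need densities for m=1..{m_cap}, got {len(densities)}"
        )
    z_normal = steady_state(scn.crypt).postmitotic
    deficits = np.empty(m_cap + 1)
    deficits[0] = 0.0
    for m in range(1, m_cap + 1):
        f = densities[m - 1]
        if z_expectation_mode and not f.point_mass:
            z_m = _expectation_mode_z(scn.crypt, scn.target, f)
        else:
            z_m = _mutated_steady_postmitotic(scn.crypt, scn.target, f.mean())
        deficits[m] = 1.0 - z_m / z_normal
    mean = mu_hat * t[:, None]
    pmf = stats.poisson.pmf(np.arange(m_cap + 1)[None, :], mean)
    fraction = 1.0 - pmf @ deficits
    slope = linear_slope(scn, summary)
    return AttritionCurve(times=t, fraction=fraction, slope_linear=slope)


def linear_slope(scn: TissueScenario, summary: FixationSummary) -> float:
    """First-order attrition slope d/dt [Z*(t)/Z_total*], per day.

    Negative for net-deleterious expected effects.  Division form requires
    the expected ratio to stay below theta = nu/lambda0; differentiation
    form requires it to stay above 1/theta (otherwise the *expected* crypt is
    already tumorigenic).
    """
    lam0 = scn.crypt.division_rate
    theta = scn.crypt.differentiation_rate / lam0
    mu = scn.dfe.mutation_rate
    r = summary.expected_ratio
    if scn.target == "division":
        if r >= theta:
            raise TumorigenicRateError(
                f"expected ratio {r} >= theta {theta}: mean crypt is tumorigenic"
            )
        return (
            -theta * lam0 * mu * summary.p_hat * scn.crypt.niche_size
            * (r - 1.0) / (r - theta)
        )
    if r <= 1.0 / theta:
        raise TumorigenicRateError(
            f"expected ratio {r} <= 1/theta {1.0 / theta}: mean crypt is tumorigenic"
        )
    return -mu * lam0 * (r - 1.0) / (theta * r - 1.0)


def human_scenarios(
    t_points: int = 76, n_grid: int = 2**13
) -> Dict[str, AttritionCurve]:
    """Linear-approximation attrition curves for the four human scenarios.

    {niche 6, niche 20} x {division, differentiation}, human colon division
    rate 1/7 per day, commitment rate from the 36-cell stem pool, 75 adult
    years.  Only the linear slope enters — the human TA/postmitotic kinetics
    never do.
    """
    out: Dict[str, AttritionCurve] = {}
    for preset in (HUMAN_COLON_NICHE6, HUMAN_COLON_NICHE20):
        for target in ("division", "differentiation"):
            scn = TissueScenario.from_preset(preset, target)
            _, summary = posterior_fixed_density(
                scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
                n_grid=n_grid, division_rate=scn.crypt.division_rate,
            )
            slope = linear_slope(scn, summary)
            t = np.linspace(0.0, preset.lifetime_days, t_points)
            out[f"{preset.name}_{target}"] = AttritionCurve(
                times=t, fraction=1.0 + slope * t, slope_linear=slope
            )
    return out
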