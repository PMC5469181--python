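"""Tumorigenesis risk and the niche-size trade-off at constant tissue output.

Tumorigenesis is defined as rate-ordering inversion inside a niche: a crypt
turns tumorigenic the moment its stem-cell division rate exceeds the
commitment-to-differentiation rate (division target: rate drifts up past nu;
differentiation target: rate drifts down past lambda), switching the crypt
from homeostasis to exponential growth.

The scan varies the niche size X1 while holding the *total* tissue output
constant: the niche holds half of the putative stem cells (so nu = 2*lambda),
and the crypt count scales as C(X1) = Z_ref_total / Z*(X1).  Small niches
need many crypts and fix mutations easily by drift; large niches select more
effectively for the rare large-effect beneficial mutations.  For
division-rate mutations these forces produce an interior niche size
minimizing tumour risk, paid for by drift-driven attrition; for neutrally
fixing differentiation-rate mutations, risk falls monotonically with niche
size while attrition is exactly niche-size invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .crypt import commitment_rate, steady_state
from .dfe import FixationSummary, RateDensity, density_sequence
from .errors import InvalidConfigurationError
from .params import _check_target
from .tissue import (
    TissueScenario,
    linear_slope,
    mutation_count_distribution,
    poisson_mutation_cap,
)

__all__ = [
    "TradeoffScanResult",
    "crossing_probability",
    "tumor_probability",
    "niche_size_scan",
]

_SCAN_N_GRID = 2**12


@dataclass
class TradeoffScanResult:
    """Per-niche-size tumour probability and end-of-life tissue change.

    ``attrition`` is the signed fractional tissue change at lifetime end
    (negative = decline); ``argmin_niche`` is the niche size minimizing the
    tumorigenesis probability.  ``excluded`` lists scanned sizes dropped for
    producing non-homeostatic baseline parameters.
    """

    niche_sizes: np.ndarray
    p_tumor: np.ndarray
    attrition: np.ndarray
    argmin_niche: int
    mode: str
    target: str
    excluded: List[int]

    def argmin_index(self) -> int:
        return int(np.argmin(self.p_tumor))


def crossing_probability(
    densities: Sequence[RateDensity],
    threshold: float,
    target: str,
) -> np.ndarray:
    """Probability q_m that the rate after m fixations is past the threshold.

    Division target: mass above ``threshold`` (= nu).  Differentiation
    target: mass below ``threshold`` (= lambda).  One value per supplied
    density, ordered by m.
    """
    _check_target(target)
    if threshold < 0:
        raise InvalidConfigurationError("threshold must be non-negative")
    out = np.empty(len(densities))
    for i, f in enumerate(densities):
        if target == "division":
            out[i] = f.mass_above(threshold)
        else:
            out[i] = 0.0 if threshold == 0.0 else f.mass_below(threshold)
    return np.clip(out, 0.0, 1.0)


def tumor_probability(
    scn: TissueScenario,
    q: Sequence[float],
    summary: FixationSummary,
    mode: str = "incremental",
) -> float:
    """Total probability of a tumorigenesis event by the end of life.

    Crypt counts ``n_m`` at ``scn.lifetime_days`` come from the Poisson
    fixation-count distribution; the per-crypt crossing probabilities ``q_m``
    are combined either as

    * ``incremental`` (default): ``P = sum_m n_m * (q_m - q_{m-1})`` — each
      crypt contributes the probability that its *latest* fixation newly
      crossed the threshold, avoiding double-counting lineages already past
      it, or
    * ``cumulative``: ``P = sum_m n_m * q_m`` — each crypt with m fixations
      contributes its full probability of sitting past the threshold.

    The sum approximation is linear in the crypt count and capped at 1; a
    warning is emitted when the cap binds.
    """
    if mode not in ("incremental", "cumulative"):
        raise InvalidConfigurationError(f"unknown aggregation mode {mode!r}")
    q = np.asarray(q, dtype=float)
    if len(q) == 0:
        return 0.0
    mu_hat = (
        summary.p_hat * scn.dfe.mutation_rate
        * scn.crypt.division_rate * scn.crypt.niche_size
    )
    n_m = mutation_count_distribution(
        mu_hat, scn.lifetime_days, scn.n_crypts, m_cap=len(q), check_tail=False
    )[1:]  # m = 1..len(q); m = 0 crypts carry no mutation
    if mode == "incremental":
        contrib = np.diff(np.concatenate([[0.0], q]))
    else:
        contrib = q
    p = float(np.sum(n_m * contrib))
    if p > 1.0:
        warnings.warn(
            f"summed tumorigenesis probability {p:.3g} exceeds 1; capping "
            "(sum approximation outside its validity range)",
            stacklevel=2,
        )
    return min(p, 1.0)


def niche_size_scan(
    base: TissueScenario,
    niche_range: Sequence[int],
    mode: str = "incremental",
    z_ref_total: Optional[float] = None,
    n_grid: int = _SCAN_N_GRID,
    half_in_niche: bool = True,
) -> TradeoffScanResult:
    """Tumour probability and attrition across stem-cell niche sizes.

    For each X1 in ``niche_range`` the niche holds half the putative stem
    cells (``nu = 2*lambda``, overridable with ``half_in_niche=False`` which
    keeps the base scenario's nu), and the crypt count is set to
    ``z_ref_total / Z*(X1)`` so total tissue output is constant.  The default
    reference output is the base scenario's own crypt count times its
    (half-in-niche) per-crypt output; ``argmin_niche`` and ``attrition`` are
    invariant to this scale.

    Differentiation-target runs share the fixation densities, crossing
    probabilities, and slope across all niche sizes (neutral fixation), so
    only the crypt count varies.
    """
    niche_range = [int(x) for x in niche_range]
    if any(x < 2 for x in niche_range):
        raise InvalidConfigurationError("scanned niche sizes must be >= 2")
    lam = base.crypt.division_rate
    t_max = base.lifetime_days

    def crypt_for(x1: int):
        if half_in_niche:
            nu = commitment_rate(lam, x1, 2 * x1)  # = 2*lambda
        else:
            nu = base.crypt.differentiation_rate
        return base.crypt.with_niche_size(x1).with_differentiation_rate(nu)

    if z_ref_total is None:
        z_ref_total = base.n_crypts * steady_state(crypt_for(base.crypt.niche_size)).postmitotic

    sizes, p_tum, attr, excluded = [], [], [], []
    shared = None  # differentiation-target densities/q are niche-size free
    for x1 in niche_range:
        crypt = crypt_for(x1)
        if not crypt.is_homeostatic:
            excluded.append(x1)
            warnings.warn(f"niche size {x1}: non-homeostatic parameters, excluded",
                          stacklevel=2)
            continue
        n_crypts = z_ref_total / steady_state(crypt).postmitotic
        scn = TissueScenario(
            crypt=crypt, dfe=base.dfe, target=base.target,
            lifetime_days=t_max, n_crypts=n_crypts,
        )
        threshold = (
            crypt.differentiation_rate if base.target == "division"
            else crypt.division_rate
        )
        if base.target == "differentiation" and shared is not None and half_in_niche:
            q, summary0, x1_first = shared
            # Neutral fixation: p_hat = 1/X1, so rescale from the first size;
            # the product p_hat * X1 (and hence mu_hat) is niche-size free.
            summary = FixationSummary(
                p_hat=summary0.p_hat * x1_first / x1,
                expected_ratio=summary0.expected_ratio,
                mu_hat=summary0.mu_hat,
            )
        else:
            r0 = scn.baseline_rate
            # Poisson depth first (needs p_hat; a coarse grid is plenty),
            # then the full density sequence.
            from .dfe import posterior_fixed_density

            _, summary = posterior_fixed_density(
                r0, x1, base.dfe, base.target, n_grid=2**10, division_rate=lam
            )
            mu_hat = summary.p_hat * base.dfe.mutation_rate * lam * x1
            m_cap = max(1, poisson_mutation_cap(mu_hat, t_max))
            densities, summary, _ = density_sequence(
                r0, x1, base.dfe, base.target, m_max=m_cap,
                n_grid=n_grid, cover_threshold=threshold, division_rate=lam,
            )
            q = crossing_probability(densities, threshold, base.target)
            if base.target == "differentiation":
                shared = (q, summary, x1)
        p_tum.append(tumor_probability(scn, q, summary, mode=mode))
        attr.append(linear_slope(scn, summary) * t_max)
        sizes.append(x1)

    if not sizes:
        raise InvalidConfigurationError("no homeostatic niche sizes in the scan range")
    sizes_a = np.asarray(sizes)
    p_a = np.asarray(p_tum)
    return TradeoffScanResult(
        niche_sizes=sizes_a,
        p_tumor=p_a,
        attrition=np.asarray(attr),
        argmin_niche=int(sizes_a[np.argmin(p_a)]),
        mode=mode,
        target=base.target,
        excluded=excluded,
    )
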