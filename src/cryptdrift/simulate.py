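"""Exact stochastic counterparts of the analytic pipeline.

Three simulators serve as independent oracles:

* :func:`gillespie_crypt` — exact (first-reaction) realizations of the crypt
  compartment birth-death system, whose ensemble means must match the ODE
  solution of :func:`cryptdrift.crypt.integrate_means`;
* :func:`ring_fixation` — continuous-time competition of a single mutant
  lineage on a one-dimensional ring of niche cells, each cell dividing at
  its own rate and replacing a uniformly chosen adjacent neighbour, whose
  fixation frequency must match the analytic ring-Moran formula, and whose
  division bookkeeping validates the one-mutation-at-a-time assumption;
* :func:`serial_ratchet` — the stochastic Muller's-ratchet counterpart of
  the fixation-density recursion: draw a mutant from the DFE, accept with
  the fixation probability, update the baseline, repeat.

All simulators draw from ``numpy.random.default_rng(seed)``; identical seed
and configuration give bit-identical results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .crypt import steady_state
from .errors import InvalidConfigurationError
from .params import CryptParameters, DFEParameters, _check_target

__all__ = [
    "SimConfig",
    "FixationOutcome",
    "RingFixationResult",
    "CryptEnsemble",
    "gillespie_crypt",
    "ring_fixation",
    "serial_ratchet",
]

_POPULATION_GUARD = 1_000_000


@dataclass(frozen=True)
class SimConfig:
    """Stochastic run configuration; the seed is recorded in all outputs."""

    seed: int
    replicates: int = 1000
    t_max: Optional[float] = None
    max_events: Optional[int] = None
    report_times: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise InvalidConfigurationError("replicates must be >= 1")


@dataclass
class FixationOutcome:
    """Fate of one mutant lineage on the ring."""

    fixed: bool
    sweep_time: float
    divisions_during_sweep: int
    mutations_expected: Optional[float] = None  # divisions * mu


@dataclass
class RingFixationResult:
    """Ensemble summary of ring-Moran lineage competitions."""

    seed: int
    niche_size: int
    relative_rate: float
    replicates: int
    n_fixed: int
    mean_sweep_time: float          # over all decided lineages, days
    mean_fixation_time: float       # conditional on fixation, days
    mean_divisions: float           # over all decided lineages
    expected_mutations_per_sweep: Optional[float]
    outcomes: Optional[list] = field(default=None, repr=False)

    @property
    def fixation_frequency(self) -> float:
        return self.n_fixed / self.replicates

    @property
    def frequency_se(self) -> float:
        p = self.fixation_frequency
        return math.sqrt(max(p * (1.0 - p), 1e-300) / self.replicates)


@dataclass
class CryptEnsemble:
    """Ensemble means and standard errors of the crypt pools over time."""

    seed: int
    replicates: int
    times: np.ndarray
    pool_names: list
    means: np.ndarray   # (n_times, n_pools)
    ses: np.ndarray     # (n_times, n_pools)


# ---------------------------------------------------------------------------
# Gillespie simulation of the crypt compartment system
# ---------------------------------------------------------------------------

def gillespie_crypt(
    params: CryptParameters,
    cfg: SimConfig,
    init: Optional[Sequence[float]] = None,
) -> CryptEnsemble:
    """Exact stochastic realizations of the crypt transition-rate system.

    Transitions (niche census X1 held fixed):

    * niche division:       X2 -> X2 + 1       at rate lambda * X1
    * displaced division:   X2 -> X2 + 1       at rate lambda * X2
    * commitment:           X2 - 1, Y1 + 1     at rate nu * X2
    * TA division:          Yi - 1, Yi+1 + 2   at rate gamma * Yi  (YR feeds Z)
    * apoptosis:            Z -> Z - 1         at rate delta * Z

    ``init`` defaults to the rounded deterministic steady state; pass zeros
    to watch the filling transient.  Reports ensemble means and standard
    errors at ``cfg.report_times``.
    """
    if cfg.t_max is None and cfg.report_times is None:
        raise InvalidConfigurationError("need t_max or report_times")
    if cfg.report_times is not None:
        report = np.asarray(cfg.report_times, dtype=float)
    else:
        report = np.linspace(0.0, cfg.t_max, 11)[1:]
    R = params.ta_rounds
    n_pools = R + 2  # x2, y1..yR, z
    if init is None:
        ss = steady_state(params)
        init_state = [round(ss.displaced)] + [round(y) for y in ss.ta_pools] + [
            round(ss.postmitotic)
        ]
    else:
        if len(init) != n_pools:
            raise InvalidConfigurationError(f"init must have length {n_pools}")
        init_state = [int(round(v)) for v in init]

    lam, nu = params.division_rate, params.differentiation_rate
    gam, delta = params.ta_division_rate, params.death_rate
    x1 = params.niche_size
    rng = np.random.default_rng(cfg.seed)

    samples = np.empty((cfg.replicates, len(report), n_pools))
    max_events = cfg.max_events or 10**9
    for rep in range(cfg.replicates):
        state = list(init_state)
        t = 0.0
        k_report = 0
        u = rng.random
        exp = rng.exponential
        events = 0
        while k_report < len(report):
            x2 = state[0]
            z = state[-1]
            rates = [lam * x1 + lam * x2, nu * x2]
            rates += [gam * state[1 + i] for i in range(R)]
            rates.append(delta * z)
            total = sum(rates)
            dt = exp(1.0 / total) if total > 0 else float("inf")
            t_next = t + dt
            while k_report < len(report) and report[k_report] < t_next:
                samples[rep, k_report] = state
                k_report += 1
            if k_report >= len(report):
                break
            t = t_next
            pick = u() * total
            acc = 0.0
            for idx, rt in enumerate(rates):
                acc += rt
                if pick < acc:
                    break
            if idx == 0:                    # stem division (niche or displaced)
                state[0] += 1
            elif idx == 1:                  # commitment to differentiation
                state[0] -= 1
                state[1] += 1
            elif idx < 2 + R:               # TA division round
                i = idx - 2
                state[1 + i] -= 1
                state[2 + i] += 2           # last round feeds z (index R+1)
            else:                           # apoptosis
                state[-1] -= 1
            events += 1
            if sum(state) > _POPULATION_GUARD:
                raise InvalidConfigurationError(
                    f"population exploded past {_POPULATION_GUARD} cells at t={t:.2f}"
                )
            if events > max_events:
                raise InvalidConfigurationError("max_events exceeded before t_end")
    means = samples.mean(axis=0)
    ses = samples.std(axis=0, ddof=1) / math.sqrt(cfg.replicates)
    names = ["x2"] + [f"y{i + 1}" for i in range(R)] + ["z"]
    return CryptEnsemble(
        seed=cfg.seed, replicates=cfg.replicates, times=report,
        pool_names=names, means=means, ses=ses,
    )


# ---------------------------------------------------------------------------
# Ring-Moran fixation dynamics
# ---------------------------------------------------------------------------

def ring_fixation(
    niche_size: int,
    r: float,
    cfg: SimConfig,
    resident_rate: float = 1.0,
    mu: Optional[float] = None,
    directed: bool = False,
    keep_outcomes: bool = False,
) -> RingFixationResult:
    """Competition of one mutant lineage on a ring of niche cells.

    A single mutant with division rate ``r * resident_rate`` starts among
    ``niche_size - 1`` residents.  Each cell divides at its own rate; the
    divider's offspring replaces an adjacent neighbour, chosen left/right
    with equal probability (``directed=True`` always replaces clockwise).
    Runs until the mutant lineage fixes or is lost.

    ``sweep_time`` is in units of ``1/resident_rate`` days (pass the niche
    division rate lambda for calendar time).  With ``mu`` given, the
    expected number of new fitness-affecting mutations arising anywhere in
    the niche while the lineage segregates is ``mu`` times the division
    count, averaged over all decided lineages.
    """
    if niche_size < 2:
        raise InvalidConfigurationError("ring needs at least 2 cells")
    if r <= 0 or resident_rate <= 0:
        raise InvalidConfigurationError("rates must be strictly positive")
    rng = np.random.default_rng(cfg.seed)
    u = rng.random
    n = niche_size
    n_fixed = 0
    tot_time = 0.0
    tot_fix_time = 0.0
    tot_div = 0
    outcomes = [] if keep_outcomes else None
    for _ in range(cfg.replicates):
        # The mutant set stays a contiguous arc under neighbour replacement:
        # track its start position and length instead of the full ring.
        start = 0
        k = 1
        t = 0.0
        divisions = 0
        while 0 < k < n:
            total = (k * r + (n - k)) * resident_rate
            t += -math.log(1.0 - u()) / total
            divisions += 1
            pick = u() * (k * r + (n - k))
            if pick < k * r:
                j = int(pick / r)           # j-th mutant along the arc
                pos = (start + j) % n
                is_mut = True
            else:
                j = int(pick - k * r)       # j-th resident clockwise from arc end
                pos = (start + k + j) % n
                is_mut = False
            right = True if directed else (u() < 0.5)
            tgt = (pos + 1) % n if right else (pos - 1) % n
            tgt_is_mut = ((tgt - start) % n) < k
            # Only replacements of the opposite type change the composition,
            # and they always act at an arc boundary, keeping it contiguous.
            if is_mut and not tgt_is_mut:
                if tgt == (start - 1) % n:
                    start = tgt
                k += 1
            elif (not is_mut) and tgt_is_mut:
                if tgt == start:
                    start = (start + 1) % n
                k -= 1
        fixed = k == n
        n_fixed += int(fixed)
        tot_time += t
        tot_div += divisions
        if fixed:
            tot_fix_time += t
        if keep_outcomes:
            outcomes.append(
                FixationOutcome(
                    fixed=fixed, sweep_time=t, divisions_during_sweep=divisions,
                    mutations_expected=(mu * divisions if mu is not None else None),
                )
            )
    reps = cfg.replicates
    return RingFixationResult(
        seed=cfg.seed,
        niche_size=n,
        relative_rate=r,
        replicates=reps,
        n_fixed=n_fixed,
        mean_sweep_time=tot_time / reps,
        mean_fixation_time=(tot_fix_time / n_fixed) if n_fixed else float("nan"),
        mean_divisions=tot_div / reps,
        expected_mutations_per_sweep=(mu * tot_div / reps if mu is not None else None),
        outcomes=outcomes,
    )


# ---------------------------------------------------------------------------
# Serial fixation ratchet
# ---------------------------------------------------------------------------

def serial_ratchet(
    niche_size: int,
    dfe: DFEParameters,
    cfg: SimConfig,
    n_fixations: int = 5,
    target: str = "division",
    r0: float = 1.0,
) -> np.ndarray:
    """Stochastic accumulation of successive fixed mutations in one niche.

    Repeatedly draws a mutational effect from the (truncation-conditioned)
    mirrored-exponential DFE, accepts it with the ring-Moran fixation
    probability (division target) or neutrally with 1/X1 (differentiation
    target), and updates the baseline rate.  Returns an array of shape
    ``(replicates, n_fixations + 1)`` holding the niche rate after
    0..n_fixations fixations; the ensemble mean is the Monte-Carlo
    counterpart of the analytic recursion's expected rate.
    """
    _check_target(target)
    if n_fixations < 0:
        raise InvalidConfigurationError("n_fixations must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    reps = cfg.replicates
    rates = np.full(reps, float(r0))
    out = np.empty((reps, n_fixations + 1))
    out[:, 0] = rates

    def draw_factor(size: int) -> np.ndarray:
        ben = rng.random(size) < dfe.beneficial_fraction
        fac = np.empty(size)
        if target == "division":
            fac[ben] = 1.0 + rng.exponential(dfe.mean_beneficial_effect, ben.sum())
            d = (~ben).sum()
            # Deleterious factors conditioned on staying positive.
            x = 1.0 - rng.exponential(dfe.mean_deleterious_effect, d)
            while np.any(x <= 0):
                bad = x <= 0
                x[bad] = 1.0 - rng.exponential(dfe.mean_deleterious_effect, bad.sum())
            fac[~ben] = x
        else:
            fac[~ben] = 1.0 + rng.exponential(dfe.mean_deleterious_effect, (~ben).sum())
            b = ben.sum()
            x = 1.0 - rng.exponential(dfe.mean_beneficial_effect, b)
            while np.any(x <= 0):
                bad = x <= 0
                x[bad] = 1.0 - rng.exponential(dfe.mean_beneficial_effect, bad.sum())
            fac[ben] = x
        return fac

    from .dfe import fixation_probability

    for m in range(1, n_fixations + 1):
        pending = np.ones(reps, dtype=bool)
        new_rates = rates.copy()
        while pending.any():
            idx = np.flatnonzero(pending)
            fac = draw_factor(len(idx))
            if target == "division":
                pfix = fixation_probability(fac, niche_size)
            else:
                pfix = np.full(len(idx), 1.0 / niche_size)
            accept = rng.random(len(idx)) < pfix
            new_rates[idx[accept]] = rates[idx[accept]] * fac[accept]
            pending[idx[accept]] = False
        rates = new_rates
        out[:, m] = rates
    return out
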