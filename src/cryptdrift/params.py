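"""Parameter containers for the crypt compartment model and the mutation DFE.

The crypt is modelled as a chain of cell compartments: a fixed-size stem-cell
niche (``X1``) whose cells divide symmetrically, a displaced stem-cell pool
(``X2``) that both divides and commits to differentiation, ``R`` rounds of
transit-amplifying (TA) doubling, and a terminally differentiated postmitotic
pool that turns over by apoptosis.  Mutational input is described by a
mirrored-exponential distribution of fitness effects (DFE) acting
multiplicatively on either the division rate or the differentiation rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidConfigurationError

__all__ = ["CryptParameters", "DFEParameters", "MutationTarget"]


# Valid mutation targets: which stem-cell rate a mutation perturbs.
DIVISION = "division"
DIFFERENTIATION = "differentiation"
MutationTarget = str  # "division" | "differentiation"


def _check_target(target: str) -> str:
    if target not in (DIVISION, DIFFERENTIATION):
        raise InvalidConfigurationError(
            f"mutation target must be 'division' or 'differentiation', got {target!r}"
        )
    return target


@dataclass(frozen=True)
class CryptParameters:
    """Rate constants and population sizes of a single crypt system.

    Attributes
    ----------
    niche_size : int
        Number of stem cells in the niche (X1) competing by symmetric division.
    division_rate : float
        Symmetric division rate of stem cells (lambda), per day.  Applies to
        both niche and displaced stem cells.
    differentiation_rate : float
        Rate at which displaced stem cells commit to differentiation and join
        the first TA pool (nu), per day.
    ta_division_rate : float
        Division rate of transit-amplifying cells (gamma), per day.
    death_rate : float
        Apoptosis rate of terminally differentiated postmitotic cells (delta),
        per day.
    ta_rounds : int
        Number of rounds of TA doubling (R) before terminal differentiation.

    Notes
    -----
    Homeostasis requires ``differentiation_rate > division_rate``; otherwise
    the displaced pool grows without bound (the model's definition of
    tumorigenesis).  Such parameter sets are legal to construct — they are the
    object of study in :mod:`cryptdrift.tradeoff` — but ``is_homeostatic`` is
    False and steady-state queries raise :class:`NonHomeostaticError`.
    """

    niche_size: int
    division_rate: float
    differentiation_rate: float
    ta_division_rate: float
    death_rate: float
    ta_rounds: int

    def __post_init__(self) -> None:
        if self.niche_size < 1 or int(self.niche_size) != self.niche_size:
            raise InvalidConfigurationError(
                f"niche_size must be a positive integer, got {self.niche_size}"
            )
        if self.ta_rounds < 1 or int(self.ta_rounds) != self.ta_rounds:
            raise InvalidConfigurationError(
                f"ta_rounds must be a positive integer, got {self.ta_rounds}"
            )
        for name in ("division_rate", "differentiation_rate", "ta_division_rate", "death_rate"):
            if getattr(self, name) <= 0:
                raise InvalidConfigurationError(f"{name} must be strictly positive")

    @property
    def is_homeostatic(self) -> bool:
        """True when the crypt admits a finite steady state (nu > lambda)."""
        return self.differentiation_rate > self.division_rate

    def with_division_rate(self, rate: float) -> "CryptParameters":
        """Copy with a mutated stem-cell division rate."""
        return CryptParameters(
            self.niche_size, rate, self.differentiation_rate,
            self.ta_division_rate, self.death_rate, self.ta_rounds,
        )

    def with_differentiation_rate(self, rate: float) -> "CryptParameters":
        """Copy with a mutated commitment-to-differentiation rate."""
        return CryptParameters(
            self.niche_size, self.division_rate, rate,
            self.ta_division_rate, self.death_rate, self.ta_rounds,
        )

    def with_niche_size(self, niche_size: int) -> "CryptParameters":
        """Copy with a different stem-cell niche size."""
        return CryptParameters(
            niche_size, self.division_rate, self.differentiation_rate,
            self.ta_division_rate, self.death_rate, self.ta_rounds,
        )


@dataclass(frozen=True)
class DFEParameters:
    """Mirrored-exponential distribution of mutational fitness effects.

    A fitness-affecting mutation multiplies the targeted stem-cell rate by a
    random factor.  With probability ``beneficial_fraction`` the mutation is
    beneficial and the factor's displacement from 1 is exponential with mean
    ``mean_beneficial_effect``; otherwise it is deleterious with mean
    displacement ``mean_deleterious_effect``.  Effects are expressed as
    dimensionless fractions of the baseline rate.

    Attributes
    ----------
    mutation_rate : float
        Rate of fitness-affecting mutation per cell division (mu).
    mean_deleterious_effect : float
        Expected deleterious effect size (s_minus).
    mean_beneficial_effect : float
        Expected beneficial effect size (s_plus).
    beneficial_fraction : float
        Probability that a fitness-affecting mutation is beneficial (P_B).
    """

    mutation_rate: float
    mean_deleterious_effect: float
    mean_beneficial_effect: float
    beneficial_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beneficial_fraction < 1.0:
            raise InvalidConfigurationError("beneficial_fraction must lie in (0, 1)")
        if self.mean_deleterious_effect <= 0 or self.mean_beneficial_effect <= 0:
            raise InvalidConfigurationError("effect scales must be strictly positive")
        if self.mutation_rate <= 0:
            raise InvalidConfigurationError("mutation_rate must be strictly positive")

    @property
    def beta(self) -> float:
        """Exponential shape of the deleterious branch, 1/s_minus."""
        return 1.0 / self.mean_deleterious_effect

    @property
    def alpha(self) -> float:
        """Exponential shape of the beneficial branch, 1/s_plus."""
        return 1.0 / self.mean_beneficial_effect
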