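"""Scenario presets for the mouse small intestine and the human colon.

Each preset bundles a crypt parameterization, the yeast-derived DFE used for
all fitness-effect calculations, and a post-adulthood observation window.
Every numeric value carries its literature provenance in ``notes``.

Presets can also be loaded from flat YAML files via :func:`load_scenario`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import yaml

from .crypt import commitment_rate
from .errors import InvalidConfigurationError
from .params import CryptParameters, DFEParameters

__all__ = [
    "ScenarioPreset",
    "YEAST_DFE",
    "MOUSE_SI",
    "HUMAN_COLON_NICHE6",
    "HUMAN_COLON_NICHE20",
    "PRESETS",
    "get_preset",
    "load_scenario",
]


@dataclass(frozen=True)
class ScenarioPreset:
    """An organism-scale scenario: crypt rates, DFE, and lifetime.

    Attributes
    ----------
    crypt_count : float
        Order-of-magnitude number of crypts in the tissue, used only for
        absolute tumorigenesis probabilities; all attrition quantities are
        normalized and independent of it.
    in_crypt_postmitotic : float
        Reporting constant: postmitotic cells residing inside the crypt
        rather than on the villus/lumenal surface.
    """

    name: str
    organism: str
    crypt: CryptParameters
    dfe: DFEParameters
    lifetime_days: float
    crypt_count: float
    in_crypt_postmitotic: float = 0.0
    notes: Dict[str, str] = field(default_factory=dict)


#: Mutation parameters measured in a Saccharomyces cerevisiae mutation
#: accumulation experiment; the standard parameter choice for all scenarios.
YEAST_DFE = DFEParameters(
    mutation_rate=1.26e-4,
    mean_deleterious_effect=0.217,
    mean_beneficial_effect=0.061,
    beneficial_fraction=0.0575,
)

_YEAST_NOTES = {
    "dfe.mutation_rate": "1.26e-4 fitness-affecting mutations per division, "
    "S. cerevisiae MA experiment (Joseph & Hall 2004)",
    "dfe.mean_beneficial_effect": "6.1% expected beneficial effect (Joseph & Hall 2004)",
    "dfe.beneficial_fraction": "5.75% of fitness effects beneficial (Joseph & Hall 2004)",
    "dfe.mean_deleterious_effect": "21.7% mean fitness decline per fixed mutation in "
    "diploid S. cerevisiae (Zeyl & DeVisser 2001)",
}

MOUSE_SI = ScenarioPreset(
    name="mouse_si",
    organism="mouse",
    crypt=CryptParameters(
        niche_size=6,
        division_rate=0.2,
        differentiation_rate=commitment_rate(0.2, 6, 15),  # = 1/3 per day
        ta_division_rate=2.0,
        death_rate=1.0 / 3.0,
        ta_rounds=6,
    ),
    dfe=YEAST_DFE,
    lifetime_days=1095.0,  # 3 years post-adulthood
    crypt_count=1.0e6,
    in_crypt_postmitotic=130.0,
    notes={
        "crypt.niche_size": "6 working stem cells, median over the mouse small "
        "intestine (Kozar et al. 2013)",
        "crypt.division_rate": "0.2 symmetric divisions/day (Kozar et al. 2013)",
        "crypt.differentiation_rate": "derived: holds the 15-cell LGR5+ pool steady "
        "(total from Snippert et al. 2010; Clevers 2013)",
        "crypt.ta_division_rate": "TA cells divide twice a day (Potten & Loeffler 1990)",
        "crypt.death_rate": "terminally differentiated cells live ~3 days "
        "(Snippert et al. 2010)",
        "crypt.ta_rounds": "~6 generations of TA amplification (Marshman et al. 2002)",
        "lifetime_days": "3 years of adult life",
        "crypt_count": "order-of-magnitude mouse small-intestinal crypt census; "
        "absolute tumour probabilities scale with it",
        "in_crypt_postmitotic": "250 cells/crypt minus 95 TA, 15 stem, 10 Paneth "
        "(Potten & Loeffler 1987; Clevers 2013)",
        **_YEAST_NOTES,
    },
)


def _human_crypt(niche_size: int) -> CryptParameters:
    lam = 1.0 / 7.0
    return CryptParameters(
        niche_size=niche_size,
        division_rate=lam,
        differentiation_rate=commitment_rate(lam, niche_size, 36),
        # TA/postmitotic kinetics are not reliably measured in humans; the
        # linear attrition slopes do not depend on them, so the mouse values
        # stand in for full-trajectory calculations.
        ta_division_rate=2.0,
        death_rate=1.0 / 3.0,
        ta_rounds=6,
    )


_HUMAN_NOTES = {
    "crypt.division_rate": "human colon stem cells divide ~once a week "
    "(Nicolas et al. 2007; Potten et al. 1992)",
    "crypt.differentiation_rate": "derived: holds the ~36-cell putative stem pool "
    "steady (Bravo & Axelrod 2013)",
    "lifetime_days": "75 years of adult life",
    "crypt_count": "order-of-magnitude human colonic crypt census",
    **_YEAST_NOTES,
}

HUMAN_COLON_NICHE6 = ScenarioPreset(
    name="human_colon_niche6",
    organism="human",
    crypt=_human_crypt(6),
    dfe=YEAST_DFE,
    lifetime_days=27375.0,  # 75 years
    crypt_count=1.0e7,
    notes={
        "crypt.niche_size": "low estimate of the human colonic niche, 6 cells "
        "(Baker et al. 2014)",
        **_HUMAN_NOTES,
    },
)

HUMAN_COLON_NICHE20 = ScenarioPreset(
    name="human_colon_niche20",
    organism="human",
    crypt=_human_crypt(20),
    dfe=YEAST_DFE,
    lifetime_days=27375.0,
    crypt_count=1.0e7,
    notes={
        "crypt.niche_size": "high estimate of the human colonic niche, 20 cells "
        "(Nicolas et al. 2007)",
        **_HUMAN_NOTES,
    },
)

PRESETS: Dict[str, ScenarioPreset] = {
    p.name: p for p in (MOUSE_SI, HUMAN_COLON_NICHE6, HUMAN_COLON_NICHE20)
}


def get_preset(name: str) -> ScenarioPreset:
    """Look up a named preset (mouse_si, human_colon_niche6, human_colon_niche20)."""
    try:
        return PRESETS[name]
    except KeyError:
        raise InvalidConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def load_scenario(path: str, name: Optional[str] = None) -> ScenarioPreset:
    """Load a scenario from a flat YAML mapping.

    Expected keys: ``organism``, ``niche_size``, ``division_rate``,
    ``differentiation_rate`` (or ``total_stem`` to derive it),
    ``ta_division_rate``, ``death_rate``, ``ta_rounds``, ``lifetime_days``,
    ``crypt_count``, and the four DFE fields ``mutation_rate``,
    ``mean_deleterious_effect``, ``mean_beneficial_effect``,
    ``beneficial_fraction``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidConfigurationError(f"scenario file {path} must be a flat mapping")
    try:
        if "differentiation_rate" in raw:
            nu = float(raw["differentiation_rate"])
        else:
            nu = commitment_rate(
                float(raw["division_rate"]), int(raw["niche_size"]), float(raw["total_stem"])
            )
        crypt = CryptParameters(
            niche_size=int(raw["niche_size"]),
            division_rate=float(raw["division_rate"]),
            differentiation_rate=nu,
            ta_division_rate=float(raw["ta_division_rate"]),
            death_rate=float(raw["death_rate"]),
            ta_rounds=int(raw["ta_rounds"]),
        )
        dfe = DFEParameters(
            mutation_rate=float(raw["mutation_rate"]),
            mean_deleterious_effect=float(raw["mean_deleterious_effect"]),
            mean_beneficial_effect=float(raw["mean_beneficial_effect"]),
            beneficial_fraction=float(raw["beneficial_fraction"]),
        )
        return ScenarioPreset(
            name=name or raw.get("name", "custom"),
            organism=str(raw.get("organism", "custom")),
            crypt=crypt,
            dfe=dfe,
            lifetime_days=float(raw["lifetime_days"]),
            crypt_count=float(raw.get("crypt_count", 1.0)),
            in_crypt_postmitotic=float(raw.get("in_crypt_postmitotic", 0.0)),
            notes={"source": path},
        )
    except KeyError as exc:
        raise InvalidConfigurationError(f"scenario file {path} is missing key {exc}") from None
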