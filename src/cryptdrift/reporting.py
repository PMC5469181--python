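"""End-to-end report tables tying the pipeline stages together.

:func:`run_report` recomputes every headline quantity of the analysis —
derived commitment rates, crypt steady states, villus arithmetic, attrition
percentages, and optionally the trade-off scan argmin — from the named
presets, tagging each row with its provenance.  Tables are plain
:class:`pandas.DataFrame` objects; :func:`write_tsv` adds a diff-able header
comment block (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .crypt import steady_state
from .dfe import posterior_fixed_density
from .presets import get_preset
from .tissue import TissueScenario, linear_slope
from .tradeoff import niche_size_scan

__all__ = ["run_report", "write_tsv"]


def _rows_for_preset(preset, include_tradeoff: bool, scan_mode: str):
    rows = []
    crypt = preset.crypt

    def add(quantity, value, units, source):
        rows.append(
            {
                "preset": preset.name,
                "quantity": quantity,
                "value": value,
                "units": units,
                "source": source,
            }
        )

    add(
        "nu",
        crypt.differentiation_rate,
        "per day",
        preset.notes.get("crypt.differentiation_rate", "derived"),
    )
    if crypt.is_homeostatic:
        ss = steady_state(crypt)
        add("X2_star", ss.displaced, "cells", "displaced-pool steady state")
        for i, y in enumerate(ss.ta_pools):
            add(f"Y{i + 1}_star", y, "cells", "TA-pool steady state")
        add("Y_total_star", ss.ta_total, "cells", "TA-pool steady state")
        add("Z_star", ss.postmitotic, "cells", "postmitotic closed form")
        if preset.in_crypt_postmitotic:
            villus = ss.postmitotic - preset.in_crypt_postmitotic
            add("villus_cells_per_crypt", villus, "cells",
                "Z* minus in-crypt postmitotic cells")
            add("villus_total_8_crypts", 8 * villus, "cells",
                "8 crypts per villus")

    for target in ("division", "differentiation"):
        scn = TissueScenario.from_preset(preset, target)
        _, summary = posterior_fixed_density(
            scn.baseline_rate, crypt.niche_size, preset.dfe, target,
            division_rate=crypt.division_rate,
        )
        add(f"p_hat_{target}", summary.p_hat, "probability",
            "quadrature of pfix against the DFE")
        add(f"expected_ratio_{target}", summary.expected_ratio, "dimensionless",
            "first-fixation posterior mean")
        slope = linear_slope(scn, summary)
        add(f"attrition_{target}_pct", -slope * preset.lifetime_days * 100.0,
            "% decline", f"linear slope x {preset.lifetime_days:g} days")

    if include_tradeoff:
        for target in ("division", "differentiation"):
            scan = niche_size_scan(
                TissueScenario.from_preset(preset, target),
                range(2, 51),
                mode=scan_mode,
            )
            add(f"argmin_niche_{target}", scan.argmin_niche, "cells",
                f"constant-output niche scan, {scan_mode} aggregation")
    return rows


def run_report(
    preset_names: Sequence[str],
    include_tradeoff: bool = False,
    scan_mode: str = "incremental",
) -> pd.DataFrame:
    """One table of recomputed headline quantities for the named presets.

    An empty preset list yields an empty table.  ``include_tradeoff`` adds
    the (slower) niche-size-scan argmin rows.
    """
    rows = []
    for name in preset_names:
        rows.extend(_rows_for_preset(get_preset(name), include_tradeoff, scan_mode))
    return pd.DataFrame(rows, columns=["preset", "quantity", "value", "units", "source"])


def write_tsv(
    table: pd.DataFrame,
    path: str,
    seed: Optional[int] = None,
    config: Optional[dict] = None,
) -> None:
    """Write a report table as TSV with a provenance header comment block."""
    cfg_json = json.dumps(config or {}, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# cryptdrift {__version__}\n")
        fh.write(f"# config_hash: {cfg_hash}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        table.to_csv(fh, sep="\t", index=False)
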