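"""Lifetime attrition of the intestinal epithelium from mutation accumulation.

Computes the expected fractional loss of the postmitotic epithelium over the
adult lifetime for the mouse small intestine (full Poisson-over-fixations
trajectory) and the four human colon scenarios (linear-slope approximation,
which needs no human TA/postmitotic kinetics).
"""

import numpy as np

from cryptdrift import (
    MOUSE_SI,
    TissueScenario,
    density_sequence,
    human_scenarios,
    poisson_mutation_cap,
    posterior_fixed_density,
    tissue_trajectory,
)

# Mouse: full trajectory.
scn = TissueScenario.from_preset(MOUSE_SI, "division")
_, summary = posterior_fixed_density(
    scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
    division_rate=scn.crypt.division_rate,
)
m_cap = poisson_mutation_cap(summary.mu_hat, scn.lifetime_days)
densities, summary, _ = density_sequence(
    scn.baseline_rate, scn.crypt.niche_size, scn.dfe, scn.target,
    m_max=m_cap, division_rate=scn.crypt.division_rate,
)
t = np.linspace(0.0, scn.lifetime_days, 7)
curve = tissue_trajectory(scn, densities, t, summary=summary)
print("mouse small intestine, division-rate mutations, 3 adult years:")
for ti, fi in zip(curve.times, curve.fraction):
    print(f"  t={ti:6.0f} d   tissue fraction={fi:.5f}")
print(f"  decline at lifetime end: {(1 - curve.fraction[-1]) * 100:.3f}% "
      f"(linear slope predicts {-curve.slope_linear * scn.lifetime_days * 100:.3f}%)\n")

# Humans: linear slopes, 75 adult years.
print("human colon, 75 adult years (linear approximation):")
for name, curve in sorted(human_scenarios().items()):
    decline = (1.0 - curve.fraction[-1]) * 100.0
    print(f"  {name:<42} {decline:6.2f}% decline")
print(
    "\nThe 20-cell niche under selection loses ~0.5% — similar to the mouse —\n"
    "but a 6-cell niche loses ~12%, and neutrally fixing differentiation-rate\n"
    "mutations cost ~6% (20-cell) to >20% (6-cell) of the epithelium."
)
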