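"""Steady-state cell pools of a mouse small-intestinal crypt.

Builds the mouse crypt parameterization (6-cell niche dividing 0.2/day, 15
LGR5+ stem cells in total, TA cells doubling twice a day for 6 rounds,
terminally differentiated cells living ~3 days) and prints the compartment
means implied by the flux balance, plus the villus cell budget.
"""

from cryptdrift import MOUSE_SI, commitment_rate, steady_state

crypt = MOUSE_SI.crypt
print("derived commitment-to-differentiation rate nu:")
print(f"  nu = {commitment_rate(0.2, 6, 15):.3f} per day "
      "(holds the 15-cell LGR5+ pool steady)\n")

ss = steady_state(crypt)
print("steady-state pool means (cells):")
print(f"  displaced stem cells X2* : {ss.displaced:g}")
for i, y in enumerate(ss.ta_pools, start=1):
    print(f"  transit-amplifying Y{i}*  : {y:g}")
print(f"  TA total                 : {ss.ta_total:g}   (~95 cells)")
print(f"  postmitotic Z*           : {ss.postmitotic:g}")

villus = ss.postmitotic - MOUSE_SI.in_crypt_postmitotic
print(f"\nvillus budget: {ss.postmitotic:g} - 130 in-crypt = {villus:g} cells/crypt;")
print(f"8 crypts feed a villus: 8 x {villus:g} = {8 * villus:g} cells "
      "(observed villi hold ~3,500).")
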