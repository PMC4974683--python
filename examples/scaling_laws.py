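"""Diameter scaling laws and blood rheology for a coronary bifurcation.

Builds the boundary conditions of the reference LAD/first-diagonal
bifurcation: Finet's law for the mother-vessel diameter, the resting-flow
and flow-split power laws, hyperemia, Carreau viscosity and the inlet
Reynolds number.
"""

import bifurcfr as b

d_dmb, d_sb = 2.77, 2.10  # daughter diameters, mm

d_pmb = b.finet_pmb_diameter(d_dmb, d_sb)
print(f"Finet mother-vessel diameter: {d_pmb:.2f} mm")

q_rest = b.resting_flow(d_pmb)
print(f"Resting flow of a {d_pmb:.2f} mm vessel: {q_rest:.1f} mL/min")
print(f"Hyperemic flow at CFR=3: {b.hyperemic_flow(q_rest, 3.0):.1f} mL/min "
      "(the study imposes 120 mL/min)")

sb, dmb = b.diameter_flow_split(d_sb, d_dmb)
print(f"Physiological flow split DMB:SB = {dmb*100:.0f}%:{sb*100:.0f}%")

p = b.RheologyParams()
print(f"Carreau viscosity: {b.carreau_viscosity(0.0, p):.4f} Pa s at zero shear, "
      f"{b.carreau_viscosity(1e6, p):.4f} Pa s at high shear")

re = b.reynolds_number(d_pmb, 120.0, p)
print(f"Inlet Reynolds number at 120 mL/min: {re:.0f}  (laminar regime)")
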