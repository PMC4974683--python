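"""Pressure probes and FFR on a synthetic stenotic flow field.

Generates the calibrated fixture field for the most severe case (80 % SB
stenosis, 70 deg angle, 45 % SB flow) with the published pressure drops
imposed, then measures them back with the cross-section probe pipeline:
one diameter proximal to the lesion (reference, 100 mmHg) and one diameter
distal in each daughter branch.
"""

import bifurcfr as b
from bifurcfr.fields import section_flux

spec = b.BifurcationSpec(alpha_deg=70.0, stenosis_sb_pct=80.0)
flow = b.FlowConditions(split_dmb=0.55, split_sb=0.45)
field = b.stenotic_jet_field(spec, flow, dp_mb=12.60, dp_sb=85.98)
print(f"fixture field: {field.n_points} points, {len(field.cells)} tets")

cls = b.build_centerlines(spec)
probe_pmb = b.extract_section(field, cls["PMB"], 1.0, side="proximal")
probe_dmb = b.extract_section(field, cls["DMB"], 1.0, side="distal")
probe_sb = b.extract_section(field, cls["SB"], 1.0, side="distal")

p0 = b.mean_pressure(probe_pmb)
print(f"PMB reference pressure: {p0:.2f} mmHg (aortic pressure)")
for name, probe in (("DMB", probe_dmb), ("SB", probe_sb)):
    dp = b.pressure_drop(p0, probe)
    f = b.ffr(p0, b.mean_pressure(probe))
    print(f"{name}: dP = {dp:.2f} mmHg, FFR = {f:.3f}")
print("an FFR below ~0.80 marks a hemodynamically significant stenosis")

q_in = section_flux(probe_pmb)
q_out = section_flux(probe_dmb) + section_flux(probe_sb)
print(f"mass conservation: inlet {q_in:.1f} vs outlets {q_out:.1f} mL/min "
      f"({abs(q_in - q_out) / q_in * 100:.3f} % mismatch)")
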