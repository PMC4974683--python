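"""The 27-case study statistics from the packaged per-case results.

Runs the study pipeline on the published per-case table and prints the
through-origin quadratic stenosis-resistance curves dP_SB = A*Q + B*Q^2 for
the 80 % side-branch stenosis cases, the FFR_SB angle-difference table, and
the full validation report against the printed values.
"""

import bifurcfr as b

report = b.run_study(b.StudyConfig(source="table3"))
print(f"{len(report.results)} cases processed\n")

print("dP_SB-Q_SB quadratic fits, 80 % SB stenosis (A: viscous, B: Bernoulli):")
for angle in sorted(report.fits):
    f = report.fits[angle]
    print(f"  {angle:.0f} deg: dP = {f.a:.3f}*Q + {f.b:.3f}*Q^2   "
          f"(RMSE {f.rmse:.2f} mmHg, n={f.n_points})")
print("larger angles give steeper curves, i.e. higher SB stenosis resistance\n")

print("FFR_SB difference between 40 and 70 deg angles:")
print(report.angle_diffs.to_string(index=False))
print("the angle matters little at 40 % SB stenosis (0.02) but strongly at 80 % (up to 0.33)\n")

validation = b.validate_against_table3()
print(validation.summary())
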