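# bifurcfr

Pressure drops, fractional flow reserve (FFR) and helical-flow descriptors in
parametric models of stenosed coronary bifurcations.

## What this package is for

Side-branch lesions of coronary bifurcations (e.g. the LAD / first-diagonal
junction) show counter-intuitive FFR behaviour: the pressure drop across a
side-branch stenosis depends not only on its severity but also on the distal
bifurcation angle. `bifurcfr` provides a desk-scale pipeline for studying
this interplay:

* **Parametric geometry** — an idealized LAD/first-diagonal lumen built on a
  sphere (radius 56.25 mm, curvature ratio 0.03) with diameters obeying
  Finet's law (D_mother = 0.678 (D1 + D2)), configurable distal angle α and
  main-branch angle β, and eccentric raised-cosine stenoses whose plaque sits
  on the inner arc. Surfaces are tessellated watertight and can be
  self-measured (%DS, angles) by slicing.
* **Scaling-law boundary conditions** — resting flow q = 1.43 d^2.55, flow
  split Q_SB/Q_DMB = (d_SB/d_DMB)^2.27, coronary flow reserve, Carreau
  shear-thinning blood rheology and Reynolds numbers; plus the full 27-case
  study grid (3 angles × 3 SB stenoses × 3 flow splits).
* **Field post-processing** — cross-section pressure probes one diameter
  proximal/distal to the lesion, ΔP and FFR = P_distal/P_proximal,
  weighted-least-squares vorticity, local normalized helicity
  LNH = (v·ω)/(|v||ω|) and helicity intensity (volume-averaged |v·ω|).
* **Statistics** — through-origin quadratic stenosis-resistance curves
  ΔP = A·Q + B·Q² (A: viscous/Poiseuille losses, B: convective/Bernoulli
  losses), degrees-of-freedom corrected RMSE, OLS regression with R², and
  FFR-vs-angle difference tables.
* **Synthetic data** — analytic flow fields with closed-form helicity and
  calibrated stenotic fixture fields that impose a prescribed pressure drop
  (a testable stand-in for a CFD solver, not a Navier–Stokes solution).

## Worked example

```python
import bifurcfr as b

# geometry: 70 deg distal angle, 80 % side-branch stenosis
spec = b.BifurcationSpec(alpha_deg=70, stenosis_sb_pct=80)
mesh = b.tessellate(spec, resolution=64)
print(b.measure_stenosis(mesh, "SB"))      # 81.0  (measured %DS)

# synthetic stenotic field with the published drops imposed, probed back
flow = b.FlowConditions(split_dmb=0.55, split_sb=0.45)
field = b.stenotic_jet_field(spec, flow, dp_mb=12.60, dp_sb=85.98)
cls = b.build_centerlines(spec)
p0 = b.mean_pressure(b.extract_section(field, cls["PMB"], 1.0, "proximal"))
p_sb = b.mean_pressure(b.extract_section(field, cls["SB"], 1.0, "distal"))
print(round(b.ffr(p0, p_sb), 3))           # 0.14  (severely ischemic SB)

# study statistics from the packaged 27-case results
report = b.run_study(b.StudyConfig(source="table3"))
f40, f70 = report.fits[40.0], report.fits[70.0]
print(f"dP = {f40.a:.3f}Q + {f40.b:.3f}Q^2")   # dP = 0.451Q + 0.010Q^2
print(f"dP = {f70.a:.3f}Q + {f70.b:.3f}Q^2")   # dP = 0.687Q + 0.017Q^2
```

The two fitted curves say that the same side-branch flow costs ~50 % more
driving pressure at a 70° angle than at 40° when the SB stenosis is 80 %:
the bifurcation angle itself contributes to stenosis resistance. The
FFR_SB difference between the extreme angles grows from 0.02 (40 % SB
stenosis) to 0.33 (80 % stenosis, 55:45 split), as
`report.angle_diffs` tabulates.

The scripts in `examples/` walk through each capability and print the
numbers above with one-line interpretations.

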