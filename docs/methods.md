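# Methods

## The model

The package studies an idealized left-anterior-descending / first-diagonal
coronary bifurcation with a lesion affecting all three segments (Medina
1,1,1): proximal main branch (PMB), distal main branch (DMB) and side branch
(SB). The defaults of `BifurcationSpec` are the reference population-based
dimensions: PMB diameter 3.30 mm; daughters 2.77 mm and 2.10 mm, consistent
with Finet's law D_mother = 0.678 (D1 + D2); main-branch angle β = 150°;
distal angle α ∈ {40°, 55°, 70°}; PMB healthy length 26.4 mm (eight
diameters); 12 mm of lesion per pathway; PMB/DMB diameter stenosis 60 % with
SB stenosis ∈ {40, 60, 80} %. Epicardial curvature is modelled by placing
all centerlines on a sphere of radius 56.25 mm (curvature ratio
(d/2)/R = 0.03), as great-circle arcs meeting at the carina, where the
departure tangents realize α (between DMB and SB) and β (between the
upstream PMB axis and the DMB; 180° = straight) exactly in the sphere's
tangent plane. Centerline positions therefore satisfy the sphere constraint
to machine precision.

Flow boundary conditions follow coronary scaling laws: resting flow
q = 1.43 d^2.55 (mL/min, d in mm), hyperemia as resting × CFR (CFR = 3), and
the physiological daughter split Q_SB/Q_DMB = (d_SB/d_DMB)^2.27, which gives
65 %:35 % for the reference diameters. Note an internal tension of the
source conditions: the resting-flow law gives ≈30 mL/min for d = 3.30 mm
(≈90 mL/min hyperemic), while the imposed hyperemic inlet flow of the study
is 120 mL/min. The package keeps the imposed 120 mL/min as the study
condition (a config default) and exposes the law separately. Blood is
shear-thinning Carreau (μ0 = 0.25 Pa·s, μ∞ = 0.0035 Pa·s, λ = 25 s,
n = 0.25, ρ = 1060 kg/m³); the inlet Reynolds number at 120 mL/min is ≈234.

## Geometry construction

**Lesion shape.** Severity and total length are specified, not the axial
shape; a raised-cosine diameter profile
d(s) = d_nom (1 − (pct/100)·w(u)), w = (1 − cos 2πu)/2, is used over each
lesion window. It is C¹, symmetric, reaches full severity at the mid-window
throat, and avoids pressure singularities in downstream models.

**Lesion placement.** Each branch carries its own 6 mm lesion adjacent to
the carina, set back one local diameter from it, so each pathway (PMB+DMB,
PMB+SB) sees 12 mm of lesion in total and the PMB pre-stenosis length stays
26.4 mm. A single-throat lesion centred on the carina point was rejected:
the minimum lumen would sit inside the junction, where cross-sections are
not simply connected and %DS self-measurement is ill-defined.

**Eccentricity.** The plaque occupies the inner (sphere-facing) arc: the
lumen centre is displaced toward the sphere centre by half the lost
diameter, so the outer wall stays fixed. This is the simplest one-parameter
eccentric model; the azimuthal shape of a real plaque is not modelled.

**Tessellation.** The lumen surface is an implicit canal surface — the
envelope of spheres of radius d(s)/2 swept along the offset centerlines,
union over branches, flat-capped by gated half-space cuts at the inlet and
outlets — triangulated by marching cubes. This guarantees a watertight,
single-body, consistently oriented surface for every angle/stenosis
combination, with the junction blend emerging naturally from the implicit
union. Two consequences are documented rather than hidden: (i) where the
radius varies steeply mid-lesion, the envelope is slightly wider than the
nominal profile (up to ~13 % at the steepest point of an 80 % lesion); the
throat itself is unaffected because the radius slope vanishes there, which
is what %DS measures; (ii) facet chord error biases sliced section areas
low by ~(2π/n)²/6 for n circumferential vertices, so the `resolution`
parameter (target vertices around the PMB circumference; grid spacing
h = π·d_PMB/resolution) must resolve the narrowest throat. Resolution 64
suffices for 40–60 % lesions; quantitative self-measurement tests use 104,
which keeps the 0.42 mm throat of an 80 % SB lesion within 1 percentage
point of the requested severity and one tessellation under ~10 s.

**Self-measurement.** `measure_stenosis` slices the mesh along the lesion
window, assembles section loops from plane-intersection segments, selects
the loop containing the centerline point, and reports
100 (1 − min 2√(A/π) / d_nom).

## Field post-processing

Flow fields are unstructured tetrahedral point sets (points in mm, velocity
in m/s, pressure in mmHg). Vorticity is reconstructed per point by
weighted-least-squares gradients over edge neighbourhoods (weights 1/|Δx|²),
which is exact for affine velocity fields; rank-deficient neighbourhoods are
flagged and resolved by pseudo-inverse. Local normalized helicity
LNH = (v·ω)/(|v||ω|) is clipped to [−1, 1] and set to 0 where
|v||ω| < ε = 1e−12 (SI) to avoid NaN contours. Helicity intensity is the
volume average of |v·ω| over the whole fluid domain — adopted here as the
single authoritative definition — with the helicity density averaged over
each cell's vertices before taking the absolute value.

Pressure probes are planes normal to the centerline, anchored to the lesion
window boundary: one nominal diameter proximal to the lesion start (PMB
reference, set to the 100 mmHg mean aortic pressure) and one diameter distal
to the lesion end (DMB, SB). Sections are extracted by linear interpolation
within intersected tetrahedra; per-tet polygon areas serve as quadrature
weights (area-weighted mean pressure, robust to non-uniform sampling), and
samples farther than one nominal diameter from the centerline point are
discarded so the infinite plane cannot pick up the neighbouring branch.
ΔP_MB = 100 − P_DMB, ΔP_SB = 100 − P_SB, FFR = P_distal/P_proximal.

## Synthetic data

The synthetic generators are deterministic under a fixed seed (default
20160805) and serve three roles:

* `poiseuille_field` / `helical_field` — analytic cylinder fields with
  closed-form answers (zero LNH; LNH = W/√(Ω²r²+W²) and intensity 2ΩW) used
  as oracles for the descriptor implementations.
* `stenotic_jet_field` — a tube lattice along the stenosed bifurcation
  centerlines with mass-conserving parabolic axial velocity per branch, an
  optional solid-body swirl, and a smoothstep pressure ramp that imposes the
  prescribed ΔP across each daughter's lesion window. It is a calibrated
  fixture: pressure is prescribed, not solved from momentum. It reproduces
  imposed drops through the probe pipeline to ≲0.1 % and conserves mass
  between inlet and outlets to <0.01 %, but it does not emulate jets,
  recirculation, or the dependence of helical structures on the bifurcation
  angle — its helicity intensity varies with flow split and stenosis, not
  with α. Passing tests on these fields validate the measurement pipeline,
  not the hemodynamics of real flows.
* `noisy_dpq` — Gaussian noise on a known quadratic ΔP(Q), for Monte-Carlo
  recovery tests (the noise model is a test-harness choice; the study itself
  has none).

Default lattice densities (24 points/diameter for analytic cylinders, 16 for
fixture fields) were chosen so that linear-interpolation quadrature keeps
absolute section fluxes within 0.5 % of the analytic flow; the study
pipeline uses 12 for speed, where only imposed pressures (exact by
construction) matter.

The packaged per-case table (27 cases: ΔP_MB, FFR_MB, ΔP_SB, FFR_SB at
Q_SB ∈ {30, 42, 54} mL/min) ships verbatim as the study's reference surface.
One cell is internally inconsistent as printed: case 60 %–40°–45 % has
FFR_MB = 0.881 while (100 − ΔP_MB)/100 = 0.879. The validation report
records this as a known printed-value discrepancy instead of widening the
consistency tolerance (0.0005) for the other 53 FFR cells.

## Statistics

ΔP–Q curves are fitted through the origin (ΔP(0) = 0 physically) by least
squares on [Q, Q²]; coefficients are reported to 3 decimals. The RMSE uses
the degrees-of-freedom correction √(Σr²/(n−m)) with m = 2; with three flow
levels per angle, n − m = 1. Because the input ΔP values carry ±0.005
rounding, the refitted RMSE is reproducible only to ~±0.008; checks against
reference RMSEs therefore use one unit of the last reported digit (0.01)
rather than print-precision equality. FFR angle differences are rounded to
2 decimals with exact halves toward zero — the convention that reproduces
the reference table, which contains one exact half-way entry
(0.775 − 0.640 = 0.135, reported 0.13). OLS regressions (e.g. ΔP_SB against
helicity intensity) use scipy's linregress; R² = 1 − SS_res/SS_tot.

## Problem sizes

Default test and pipeline sizes: marching-cubes tessellation at resolution
64 (≈96 k faces, ~3 s) or 104 for quantitative closure (≈255 k faces,
~10 s); fixture fields of ~30–70 k points; Monte-Carlo recovery at 1000
replicates of 3-point fits. The full 9-geometry self-measurement sweep runs
in ~2 minutes.

## Known limitations

* No Navier–Stokes solve: velocity/pressure fields are synthetic fixtures or
  externally supplied. Absolute helicity magnitudes of real CFD solutions,
  wall shear stress, transitional flow, pulsatility, wall compliance and
  microvascular/lumped-parameter effects are out of scope.
* The external field reader supports legacy-VTK ASCII tetrahedral grids
  only (XML VTU/VTP are not parsed); surface export is STL, centerline
  export legacy-VTK polyline and CSV.
* The junction blend is the implicit union of tubes; it is smooth but not a
  CAD-controlled fillet, and the plaque's azimuthal extent is idealized.
* The SB lesion length is measured along the PMB+SB pathway (6 mm in the
  SB); if interpreted as 12 mm along the SB axis alone, severities and probe
  locations would shift accordingly.
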