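"""Synthetic inputs: analytic flow fields with closed-form helicity,
calibrated stenotic fixture fields, noisy dP-Q samples, and the packaged
27-case results table.

The stenotic field generator imposes a prescribed pressure drop on a
mass-conserving axial velocity field laid out along the bifurcation
centerlines.  It is a calibrated fixture for exercising the probe/FFR
pipeline end-to-end, NOT a Navier-Stokes solution; pressure is prescribed,
not solved from momentum.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError
from .fields import FlowField
from .geometry import BifurcationSpec, _carina_frame
from .hemodynamics import FlowConditions, RheologyParams, ML_MIN_TO_M3_S, MMHG_PER_PA

#: default seed for reproducible synthetic data
DEFAULT_SEED = 20160805


@dataclass(frozen=True)
class AnalyticFieldSpec:
    """Parameters of an analytic cylindrical test field.

    ``kind`` selects the velocity model: 'poiseuille' (parabolic axial flow,
    zero helicity), or 'helical' (rigid rotation omega plus axial plug flow,
    closed-form LNH and helicity intensity).
    """

    kind: str = "poiseuille"
    radius: float = 1.65        # mm
    length: float = 20.0        # mm
    flow: float = 120.0         # mL/min
    omega: float = 1.0          # rad/s (helical)
    mesh_density: int = 24      # points per diameter
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0 or self.flow <= 0:
            raise InvalidParameterError("radius, length and flow must be positive")
        if self.mesh_density < 8:
            raise InvalidParameterError("mesh_density must be >= 8")


# ---------------------------------------------------------------------------
# tetrahedral lattice helpers


def _disk_template(n_rings: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit-disk point set (rings with counts growing linearly) and its
    Delaunay triangulation."""
    from scipy.spatial import Delaunay

    pts = [(0.0, 0.0)]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        n_k = 6 * k
        th = 2.0 * np.pi * np.arange(n_k) / n_k + (0.5 * np.pi * (k % 2)) / n_k
        pts.extend(zip(r * np.cos(th), r * np.sin(th)))
    pts = np.asarray(pts)
    tri = Delaunay(pts)
    return pts, tri.simplices


def _prisms_to_tets(tri: np.ndarray, n_layer_pts: int, n_layers: int) -> np.ndarray:
    """Split each extruded prism into 3 tets with index-sorted diagonals."""
    tets = []
    for k in range(n_layers - 1):
        lo = k * n_layer_pts
        hi = (k + 1) * n_layer_pts
        for tri_idx in np.sort(tri, axis=1):
            a, b, c = tri_idx
            tets.append((lo + a, lo + b, lo + c, hi + a))
            tets.append((lo + b, lo + c, hi + a, hi + b))
            tets.append((lo + c, hi + a, hi + b, hi + c))
    return np.asarray(tets, dtype=np.int64)


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a = points[tets[:, 0]]
    d1 = points[tets[:, 1]] - a
    d2 = points[tets[:, 2]] - a
    d3 = points[tets[:, 3]] - a
    return np.abs(np.einsum("ij,ij->i", d1, np.cross(d2, d3))) / 6.0


def _cylinder_lattice(spec: AnalyticFieldSpec):
    n_rings = max(4, spec.mesh_density // 2)
    disk, tri = _disk_template(n_rings)
    dz = spec.radius / n_rings
    n_layers = max(3, int(np.ceil(spec.length / dz)) + 1)
    z = np.linspace(0.0, spec.length, n_layers)
    n_pts = len(disk)
    xy = np.tile(disk * spec.radius, (n_layers, 1))
    zz = np.repeat(z, n_pts)
    points = np.column_stack([xy[:, 0], xy[:, 1], zz])
    tets = _prisms_to_tets(tri, n_pts, n_layers)
    return points, tets


# ---------------------------------------------------------------------------
# analytic cylinder fields


def poiseuille_field(spec: AnalyticFieldSpec) -> FlowField:
    """Fully developed laminar pipe flow along +z in a cylinder.

    v_z = 2 vbar (1 - (r/R)^2); axial pressure gradient from the analytic
    Poiseuille relation with the infinite-shear viscosity; LNH vanishes
    identically (velocity is everywhere orthogonal to vorticity).
    """
    if spec.kind != "poiseuille":
        raise InvalidParameterError("spec.kind must be 'poiseuille'")
    points, tets = _cylinder_lattice(spec)
    R = spec.radius * 1e-3
    q = spec.flow * ML_MIN_TO_M3_S
    vbar = q / (np.pi * R * R)
    r2 = (points[:, 0] ** 2 + points[:, 1] ** 2) / spec.radius ** 2
    vel = np.zeros_like(points)
    vel[:, 2] = 2.0 * vbar * (1.0 - r2)
    mu = RheologyParams().mu_inf
    dpdz = 8.0 * mu * vbar / R ** 2          # Pa/m
    p = 100.0 - dpdz * (points[:, 2] * 1e-3) * MMHG_PER_PA
    return FlowField(points=points, velocity=vel, pressure=p,
                     cells=tets, cell_volumes=_tet_volumes(points, tets))


def helical_field(spec: AnalyticFieldSpec) -> FlowField:
    """Rigid rotation plus axial plug flow: v = (-Om*y, Om*x, W).

    Vorticity is (0, 0, 2*Om) everywhere, so the helicity density v.w = 2*Om*W
    is constant: helicity intensity = |2*Om*W| and
    LNH(r) = W / sqrt(Om^2 r^2 + W^2) in closed form (r in m).
    """
    if spec.kind != "helical":
        raise InvalidParameterError("spec.kind must be 'helical'")
    points, tets = _cylinder_lattice(spec)
    R = spec.radius * 1e-3
    W = spec.flow * ML_MIN_TO_M3_S / (np.pi * R * R)
    xy_m = points[:, :2] * 1e-3
    vel = np.column_stack([-spec.omega * xy_m[:, 1], spec.omega * xy_m[:, 0],
                           np.full(len(points), W)])
    rho = RheologyParams().rho
    r2 = np.einsum("ij,ij->i", xy_m, xy_m)
    p = 100.0 + 0.5 * rho * spec.omega ** 2 * r2 * MMHG_PER_PA
    return FlowField(points=points, velocity=vel, pressure=p,
                     cells=tets, cell_volumes=_tet_volumes(points, tets))


def helical_lnh_exact(spec: AnalyticFieldSpec, r_mm) -> np.ndarray:
    """Closed-form LNH of the helical field at radius ``r_mm``."""
    R = spec.radius * 1e-3
    W = spec.flow * ML_MIN_TO_M3_S / (np.pi * R * R)
    r = np.asarray(r_mm, dtype=float) * 1e-3
    return W / np.sqrt(spec.omega ** 2 * r ** 2 + W ** 2)


# ---------------------------------------------------------------------------
# stenotic fixture field on a bifurcation


def stenotic_jet_field(spec: BifurcationSpec, flow: FlowConditions,
                       dp_mb: float, dp_sb: float,
                       mesh_density: int = 16, swirl: float = 0.3,
                       seed: int = DEFAULT_SEED) -> FlowField:
    """Calibrated stenotic flow fixture on the bifurcation centerlines.

    Lays a tube lattice along each branch following the stenosed lumen
    (effective diameter and eccentric offset), with a mass-conserving
    parabolic axial velocity carrying the branch flow, an optional solid-body
    swirl component (fraction ``swirl`` of the local mean axial speed at the
    wall), and a pressure field equal to 100 mmHg in the PMB that decreases
    smoothly by ``dp_mb`` / ``dp_sb`` across the daughter lesion windows.

    This is NOT a Navier-Stokes solution: the pressure drop is imposed, which
    makes the probe -> dP -> FFR pipeline testable against exact targets.
    """
    if dp_mb < 0 or dp_sb < 0:
        raise InvalidParameterError("prescribed pressure drops must be non-negative")
    branches = _carina_frame(spec)
    n_rings = max(4, mesh_density // 2)
    disk, tri = _disk_template(n_rings)
    n_pts = len(disk)
    rng = np.random.default_rng(seed)  # reserved for optional perturbations

    all_points, all_vel, all_press, all_tets = [], [], [], []
    offset = 0
    q_branch = {"PMB": flow.inlet_flow, "DMB": flow.q_dmb, "SB": flow.q_sb}
    dp_branch = {"PMB": 0.0, "DMB": dp_mb, "SB": dp_sb}

    for label, br in branches.items():
        ds = br.nominal / mesh_density * 2.0
        n_st = max(4, int(np.ceil(br.length / ds)) + 1)
        s = np.linspace(0.0, br.length, n_st)
        centers = np.atleast_2d(br.lumen_center(s))
        radii = 0.5 * br.effective_diameter(s)
        tang = np.atleast_2d(br.tangent(s))
        rad = np.atleast_2d(br.radial(s))
        e2 = np.cross(tang, rad)
        e2 /= np.linalg.norm(e2, axis=1, keepdims=True)

        q_si = q_branch[label] * ML_MIN_TO_M3_S
        pts = np.empty((n_st * n_pts, 3))
        vel = np.empty_like(pts)
        press = np.empty(n_st * n_pts)
        w0, w1 = br.window
        for k in range(n_st):
            sl = slice(k * n_pts, (k + 1) * n_pts)
            pts[sl] = (centers[k]
                       + radii[k] * (np.outer(disk[:, 0], rad[k]) + np.outer(disk[:, 1], e2[k])))
            r_m = radii[k] * 1e-3
            vbar = q_si / (np.pi * r_m * r_m)
            rho2 = np.einsum("ij,ij->i", disk, disk)
            axial = 2.0 * vbar * (1.0 - rho2)
            v = np.outer(axial, tang[k])
            if swirl > 0:
                e_theta = (np.outer(-disk[:, 1], rad[k]) + np.outer(disk[:, 0], e2[k]))
                v += swirl * vbar * e_theta
            vel[sl] = v
            u = np.clip((s[k] - w0) / (w1 - w0), 0.0, 1.0)
            ramp = u * u * (3.0 - 2.0 * u)  # smoothstep across the lesion
            press[sl] = 100.0 - dp_branch[label] * ramp

        tets = _prisms_to_tets(tri, n_pts, n_st) + offset
        all_points.append(pts)
        all_vel.append(vel)
        all_press.append(press)
        all_tets.append(tets)
        offset += len(pts)

    points = np.vstack(all_points)
    tets = np.vstack(all_tets)
    return FlowField(points=points, velocity=np.vstack(all_vel),
                     pressure=np.concatenate(all_press), cells=tets,
                     cell_volumes=_tet_volumes(points, tets))


# ---------------------------------------------------------------------------
# noisy dP-Q samples


def noisy_dpq(a: float, b: float, q_values, sigma: float,
              seed: int = DEFAULT_SEED) -> list:
    """dP = a*q + b*q^2 + N(0, sigma) observations, reproducible under seed."""
    from .stats import DpQPoint

    if sigma < 0:
        raise InvalidParameterError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    q = np.asarray(q_values, dtype=float)
    dp = a * q + b * q * q + rng.normal(0.0, sigma, size=len(q))
    return [DpQPoint(q=float(qi), dp=float(di)) for qi, di in zip(q, dp)]


# ---------------------------------------------------------------------------
# packaged 27-case results table

_TABLE3_CSV = """\
sb_stenosis_pct,alpha_deg,split_sb_pct,dp_mb,ffr_mb,dp_sb,ffr_sb
40,40,25,14.89,0.851,7.10,0.929
40,55,25,14.93,0.851,8.37,0.916
40,70,25,14.71,0.853,9.26,0.907
40,40,35,13.07,0.869,7.36,0.926
40,55,35,12.82,0.872,8.69,0.913
40,70,35,12.58,0.874,9.54,0.905
40,40,45,11.55,0.885,7.80,0.922
40,55,45,11.12,0.889,9.19,0.908
40,70,45,10.93,0.891,10.04,0.900
60,40,25,14.85,0.851,9.35,0.906
60,55,25,15.20,0.848,10.99,0.890
60,70,25,15.41,0.846,12.80,0.872
60,40,35,13.26,0.867,11.09,0.889
60,55,35,13.31,0.867,13.34,0.867
60,70,35,13.51,0.865,15.18,0.848
60,40,45,12.06,0.881,13.81,0.862
60,55,45,11.89,0.881,16.73,0.833
60,70,45,12.12,0.879,18.58,0.814
80,40,25,15.20,0.848,22.53,0.775
80,55,25,15.27,0.847,30.54,0.695
80,70,25,15.63,0.844,36.03,0.640
80,40,35,13.76,0.862,35.50,0.645
80,55,35,13.55,0.864,49.61,0.504
80,70,35,13.87,0.861,57.72,0.423
80,40,45,12.69,0.873,52.66,0.473
80,55,45,12.30,0.877,74.16,0.258
80,70,45,12.60,0.874,85.98,0.140
"""


def table3_fixture(inlet_flow: float = 120.0) -> pd.DataFrame:
    """The published per-case pressure-drop / FFR results, verbatim.

    Columns: case_id, sb_stenosis_pct, alpha_deg, split_sb_pct, q_sb_ml_min,
    dp_mb (mmHg), ffr_mb, dp_sb (mmHg), ffr_sb.  The side-branch flow is the
    imposed inlet flow times the SB split fraction.
    """
    from .hemodynamics import case_id

    df = pd.read_csv(io.StringIO(_TABLE3_CSV))
    df.insert(0, "case_id", [case_id(r.sb_stenosis_pct, r.alpha_deg, r.split_sb_pct / 100.0)
                             for r in df.itertuples()])
    df.insert(4, "q_sb_ml_min", inlet_flow * df["split_sb_pct"] / 100.0)
    return df
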