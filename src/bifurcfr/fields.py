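"""Hemodynamic read-outs from an unstructured flow field.

Implements the post-processing layer applied to a (real or synthetic) steady
flow solution on a tetrahedral point cloud: cross-section pressure probes one
diameter proximal/distal to a stenosis, pressure drops and fractional flow
reserve (FFR), and the helical-flow descriptors

* local normalized helicity  LNH = (v . w) / (|v||w|),  w = curl v, the
  cosine of the angle between velocity and vorticity (sign = rotation
  handedness along the flow), and
* helicity intensity, the volume average of |v . w| over the fluid domain,
  a magnitude measure of helical flow strength (m/s^2).

Units: point coordinates in mm, velocity in m/s, pressure in mmHg; vorticity
and helicity in SI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError, ProbeError
from .geometry import Centerline

#: |v||w| below this (SI) is treated as degenerate and LNH set to 0
LNH_EPS = 1e-12


@dataclass
class FlowField:
    """Unstructured sample set of a steady flow solution.

    points (n, 3) mm; velocity (n, 3) m/s; pressure (n,) mmHg;
    cells (m, 4) tetrahedral connectivity; cell_volumes (m,) mm^3.
    """

    points: np.ndarray
    velocity: np.ndarray
    pressure: np.ndarray
    cells: np.ndarray
    cell_volumes: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.points)
        if self.velocity.shape != (n, 3) or self.pressure.shape != (n,):
            raise InvalidParameterError("velocity/pressure shapes inconsistent with points")
        if self.cells.ndim != 2 or self.cells.shape[1] != 4:
            raise InvalidParameterError("cells must be (m, 4) tetrahedra")
        if len(self.cell_volumes) != len(self.cells):
            raise InvalidParameterError("cell_volumes inconsistent with cells")
        for arr in (self.points, self.velocity, self.pressure, self.cell_volumes):
            if not np.all(np.isfinite(arr)):
                raise InvalidParameterError("non-finite values in flow field")
        if np.any(self.cell_volumes <= 0):
            raise InvalidParameterError("cell volumes must be positive")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class SectionProbe:
    """Samples of the field on a cross-section plane.

    One sample per intersected tetrahedron: the polygon centroid position,
    linearly interpolated pressure/velocity, and the polygon area as weight;
    weights sum to the section area (mm^2).
    """

    branch: str
    location: float
    plane_origin: np.ndarray
    plane_normal: np.ndarray
    positions: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray
    weights: np.ndarray

    @property
    def area(self) -> float:
        return float(self.weights.sum())


# ---------------------------------------------------------------------------
# vorticity and helicity


def vorticity(fieldobj: FlowField) -> tuple[np.ndarray, np.ndarray]:
    """Point-wise vorticity (1/s) via weighted-least-squares gradients.

    For each point the velocity gradient is reconstructed from its edge
    neighbours (from the tetrahedral connectivity) by solving the weighted
    normal equations; the reconstruction is exact for affine velocity fields.
    Returns ``(omega, flagged)`` where ``flagged`` marks points whose
    neighbourhood was rank-deficient (value from a pseudo-inverse).
    """
    pts = fieldobj.points * 1e-3  # mm -> m
    vel = fieldobj.velocity
    n = fieldobj.n_points

    tet = fieldobj.cells
    pair_idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    edges = np.vstack([tet[:, [i, j]] for i, j in pair_idx])
    edges = np.unique(np.sort(edges, axis=1), axis=0)
    i = np.concatenate([edges[:, 0], edges[:, 1]])
    j = np.concatenate([edges[:, 1], edges[:, 0]])

    dx = pts[j] - pts[i]
    dv = vel[j] - vel[i]
    w = 1.0 / np.maximum(np.einsum("ij,ij->i", dx, dx), 1e-30)

    M = np.zeros((n, 3, 3))
    B = np.zeros((n, 3, 3))
    np.add.at(M, i, w[:, None, None] * dx[:, :, None] * dx[:, None, :])
    np.add.at(B, i, w[:, None, None] * dx[:, :, None] * dv[:, None, :])

    det = np.linalg.det(M)
    scale = np.einsum("ijj->i", M) ** 3 / 27.0 + 1e-300
    flagged = det < 1e-9 * scale

    G = np.empty((n, 3, 3))
    ok = ~flagged
    if np.any(ok):
        G[ok] = np.linalg.solve(M[ok], B[ok])
    if np.any(flagged):
        G[flagged] = np.linalg.pinv(M[flagged]) @ B[flagged]

    # G[a, b] = d v_b / d x_a
    omega = np.stack([G[:, 1, 2] - G[:, 2, 1],
                      G[:, 2, 0] - G[:, 0, 2],
                      G[:, 0, 1] - G[:, 1, 0]], axis=1)
    return omega, flagged


def local_normalized_helicity(fieldobj: FlowField, omega: np.ndarray | None = None,
                              eps: float = LNH_EPS) -> np.ndarray:
    """LNH = (v . w)/(|v||w|) per point, in [-1, 1]; 0 where |v||w| < eps.

    Positive/negative values mark clockwise/counter-clockwise rotating fluid
    structures along the main flow direction.
    """
    if omega is None:
        omega, _ = vorticity(fieldobj)
    v = fieldobj.velocity
    num = np.einsum("ij,ij->i", v, omega)
    den = np.linalg.norm(v, axis=1) * np.linalg.norm(omega, axis=1)
    lnh = np.where(den < eps, 0.0, num / np.maximum(den, eps))
    return np.clip(lnh, -1.0, 1.0)


def helicity_intensity(fieldobj: FlowField, omega: np.ndarray | None = None) -> float:
    """Volume-averaged |v . w| over the fluid domain (m/s^2).

    The helicity density v . w is averaged over each cell's vertices before
    taking the absolute value, then volume-weighted over all cells.
    """
    if omega is None:
        omega, _ = vorticity(fieldobj)
    vol = fieldobj.cell_volumes
    total = vol.sum()
    if total <= 0:
        raise InvalidParameterError("zero total fluid volume")
    hk = np.einsum("ij,ij->i", fieldobj.velocity, omega)  # per point
    cell_hk = hk[fieldobj.cells].mean(axis=1)
    return float(np.abs(cell_hk) @ vol / total)


# ---------------------------------------------------------------------------
# cross-section probes


def _slice_tets(fieldobj: FlowField, origin: np.ndarray, normal: np.ndarray):
    """Intersect all tets with the plane; yield per-tet polygon centroid,
    interpolated pressure/velocity and polygon area."""
    pts = fieldobj.points
    sd = (pts - origin) @ normal
    sd[sd == 0.0] = 1e-12  # points exactly on the plane: nudge to one side
    tet = fieldobj.cells
    tsd = sd[tet]
    cut = (tsd.min(axis=1) < 0.0) & (tsd.max(axis=1) > 0.0)
    if not np.any(cut):
        return None

    pair_idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    e1 = _plane_basis(normal)
    e2 = np.cross(normal, e1)

    cents, press, vels, areas = [], [], [], []
    for t in tet[cut]:
        poly, pp, pv = [], [], []
        for a, b in pair_idx:
            sa, sb = sd[t[a]], sd[t[b]]
            if (sa < 0) != (sb < 0):
                f = sa / (sa - sb)
                poly.append(pts[t[a]] + f * (pts[t[b]] - pts[t[a]]))
                pp.append(fieldobj.pressure[t[a]] + f * (fieldobj.pressure[t[b]] - fieldobj.pressure[t[a]]))
                pv.append(fieldobj.velocity[t[a]] + f * (fieldobj.velocity[t[b]] - fieldobj.velocity[t[a]]))
        if len(poly) < 3:
            continue
        poly = np.asarray(poly)
        pp = np.asarray(pp)
        pv = np.asarray(pv)
        # order polygon vertices by angle in the plane
        c0 = poly.mean(axis=0)
        ang = np.arctan2((poly - c0) @ e2, (poly - c0) @ e1)
        order = np.argsort(ang)
        poly, pp, pv = poly[order], pp[order], pv[order]
        v2 = np.column_stack([(poly - c0) @ e1, (poly - c0) @ e2])
        x, y = v2[:, 0], v2[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area <= 0:
            continue
        cents.append(poly.mean(axis=0))
        press.append(pp.mean())
        vels.append(pv.mean(axis=0))
        areas.append(area)
    if not cents:
        return None
    return (np.asarray(cents), np.asarray(press), np.asarray(vels), np.asarray(areas))


def _plane_basis(normal: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    return e1 / np.linalg.norm(e1)


def probe_plane(centerline: Centerline, offset_diameters: float, side: str) -> tuple[float, np.ndarray, np.ndarray]:
    """Arc-length station, origin and normal of a probe plane.

    ``side='proximal'`` places the plane ``offset_diameters`` nominal
    diameters before the lesion window start; ``'distal'`` the same distance
    beyond the window end.
    """
    w0, w1 = centerline.lesion_window
    d = centerline.nominal_diameter
    if side == "proximal":
        s = w0 - offset_diameters * d
    elif side == "distal":
        s = w1 + offset_diameters * d
    else:
        raise InvalidParameterError("side must be 'proximal' or 'distal'")
    if not (0.0 <= s <= centerline.arc_length[-1]):
        raise ProbeError(
            f"probe plane at s={s:.2f} mm lies outside branch {centerline.label} "
            f"extent [0, {centerline.arc_length[-1]:.2f}]")
    origin = np.asarray(centerline.position_at(s))
    normal = np.asarray(centerline.tangent_at(s))
    return s, origin, normal


def extract_section(fieldobj: FlowField, centerline: Centerline,
                    offset_diameters: float = 1.0, side: str = "distal",
                    keep_radius: float | None = None) -> SectionProbe:
    """Extract the cross-section probe one (or ``offset_diameters``) local
    diameters proximal/distal to the branch's lesion.

    The plane normal is the local centerline tangent; the field is restricted
    to the plane by linear interpolation within intersected tetrahedra, and
    samples farther than ``keep_radius`` (default: one nominal diameter) from
    the centerline point are discarded so neighbouring branches cut by the
    same infinite plane do not contaminate the probe.
    """
    s, origin, normal = probe_plane(centerline, offset_diameters, side)
    sliced = _slice_tets(fieldobj, origin, normal)
    if sliced is None:
        raise ProbeError(f"probe plane at s={s:.2f} mm does not intersect the field")
    cents, press, vels, areas = sliced
    keep_radius = centerline.nominal_diameter if keep_radius is None else keep_radius
    keep = np.linalg.norm(cents - origin, axis=1) <= keep_radius
    if not np.any(keep):
        raise ProbeError("no section samples within keep radius of the centerline")
    return SectionProbe(branch=centerline.label, location=s, plane_origin=origin,
                        plane_normal=normal, positions=cents[keep],
                        pressure=press[keep], velocity=vels[keep], weights=areas[keep])


def mean_pressure(probe: SectionProbe) -> float:
    """Area-weighted mean pressure (mmHg) over the section."""
    if len(probe.weights) == 0 or probe.weights.sum() <= 0:
        raise ProbeError("empty section probe")
    return float(probe.pressure @ probe.weights / probe.weights.sum())


def section_flux(probe: SectionProbe) -> float:
    """Volume flux through the section (mL/min), velocity dotted with the
    plane normal and integrated with the area weights."""
    vn = probe.velocity @ probe.plane_normal          # m/s
    q_m3s = float(vn @ probe.weights) * 1e-6          # mm^2 * m/s -> m^3/s
    return q_m3s * 6.0e7                              # 1 m^3/s = 6e7 mL/min


def pressure_drop(p_ref: float, probe: SectionProbe) -> float:
    """Pressure drop p_ref - <p>_section in mmHg."""
    return p_ref - mean_pressure(probe)


def ffr(p_prox: float, p_dist: float) -> float:
    """Fractional flow reserve: distal / proximal mean pressure."""
    if p_prox <= 0:
        raise InvalidParameterError("proximal pressure must be positive")
    return p_dist / p_prox
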