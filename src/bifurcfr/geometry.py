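"""Parametric stenosed coronary-bifurcation geometry.

Builds an idealized left-anterior-descending / first-diagonal bifurcation:
three centerlines (proximal main branch PMB, distal main branch DMB, side
branch SB) lying on a sphere that mimics the curvature of the epicardial
surface, diameters obeying Finet's law, and eccentric stenoses with a
raised-cosine axial profile whose plaque sits on the inner (sphere-facing)
arc of the vessel wall.

Conventions
-----------
* Lengths in mm, right-handed frame with the sphere center at the origin;
  the carina (branch point) sits at ``(0, 0, sphere_radius)``.
* The distal angle ``alpha`` is measured between the DMB and SB departure
  tangents; the main-branch angle ``beta`` between the upstream PMB axis and
  the DMB axis (180 deg = perfectly straight main vessel).
* Each branch carries a lesion of length ``lesion_length / 2`` adjacent to
  the carina (separated from it by one local diameter of clearance for the
  junction blend), so that each pathway through the bifurcation sees
  ``lesion_length`` of disease in total.

The lumen surface is realized as an implicit canal surface (the envelope of
spheres swept along the plaque-offset centerlines), flat-capped at the
inlet/outlets and triangulated with marching cubes, which guarantees a
watertight single-body mesh for every angle/stenosis combination.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

from .errors import ConstructionError, InvalidParameterError, TessellationError

FINET_COEFF = 0.678

BranchLabel = Literal["PMB", "DMB", "SB"]
BRANCHES: tuple[str, ...] = ("PMB", "DMB", "SB")


def finet_pmb_diameter(d_dmb: float, d_sb: float) -> float:
    """Mother-vessel diameter from Finet's law: 0.678 * (d_dmb + d_sb)."""
    if d_dmb < 0 or d_sb < 0:
        raise InvalidParameterError("daughter diameters must be non-negative")
    return FINET_COEFF * (d_dmb + d_sb)


@dataclass(frozen=True)
class BifurcationSpec:
    """All geometric and lesion parameters of one bifurcation case.

    Defaults reproduce the population-based LAD/first-diagonal model:
    PMB diameter 3.30 mm with daughters 2.77/2.10 mm (Finet's law),
    main-branch angle 150 deg, sphere radius 56.25 mm (curvature ratio 0.03),
    26.4 mm of healthy PMB before the lesion, 12 mm total lesion per pathway,
    60 % PMB/DMB stenosis.  Post-stenosis daughter lengths default to ten
    local diameters so the distal probe planes sit well inside the domain.
    """

    d_pmb: float = 3.30
    d_dmb: float = 2.77
    d_sb: float = 2.10
    alpha_deg: float = 70.0
    beta_deg: float = 150.0
    sphere_radius: float = 56.25
    pmb_length: float = 26.4
    lesion_length: float = 12.0
    stenosis_pmb_pct: float = 60.0
    stenosis_dmb_pct: float = 60.0
    stenosis_sb_pct: float = 60.0
    dmb_length: float | None = None
    sb_length: float | None = None

    def __post_init__(self) -> None:
        for name in ("d_pmb", "d_dmb", "d_sb"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("alpha_deg", "beta_deg"):
            if not (0 < getattr(self, name) < 180):
                raise InvalidParameterError(f"{name} must lie in (0, 180)")
        for name in ("stenosis_pmb_pct", "stenosis_dmb_pct", "stenosis_sb_pct"):
            if not (0 <= getattr(self, name) < 100):
                raise InvalidParameterError(f"{name} must lie in [0, 100)")
        if self.pmb_length <= 0 or self.lesion_length <= 0:
            raise InvalidParameterError("pmb_length and lesion_length must be positive")
        if self.sphere_radius <= self.d_pmb:
            raise InvalidParameterError("sphere_radius must exceed d_pmb")
        if self.dmb_length is None:
            object.__setattr__(self, "dmb_length", 10.0 * self.d_dmb)
        if self.sb_length is None:
            object.__setattr__(self, "sb_length", 10.0 * self.d_sb)
        if self.dmb_length <= 0 or self.sb_length <= 0:
            raise InvalidParameterError("post-stenosis branch lengths must be positive")

    # -- serialization ------------------------------------------------------
    def to_yaml(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "BifurcationSpec":
        return cls(**yaml.safe_load(io.StringIO(text)))

    # -- derived quantities -------------------------------------------------
    def nominal_diameter(self, branch: str) -> float:
        return {"PMB": self.d_pmb, "DMB": self.d_dmb, "SB": self.d_sb}[_check_branch(branch)]

    def stenosis_pct(self, branch: str) -> float:
        return {"PMB": self.stenosis_pmb_pct, "DMB": self.stenosis_dmb_pct,
                "SB": self.stenosis_sb_pct}[_check_branch(branch)]

    def branch_length(self, branch: str) -> float:
        """Total centerline arc length of a branch (mm)."""
        half = 0.5 * self.lesion_length
        branch = _check_branch(branch)
        if branch == "PMB":
            return self.pmb_length + half + self.d_pmb
        post = self.dmb_length if branch == "DMB" else self.sb_length
        return self.nominal_diameter(branch) + half + post

    def lesion_window(self, branch: str) -> tuple[float, float]:
        """Arc-length interval of the branch's lesion (mm).

        PMB arc length runs from the inlet; daughter arc lengths run from the
        carina.  Each branch lesion spans half the per-pathway lesion length
        and is set back one local diameter from the carina.
        """
        half = 0.5 * self.lesion_length
        branch = _check_branch(branch)
        if branch == "PMB":
            return (self.pmb_length, self.pmb_length + half)
        d = self.nominal_diameter(branch)
        return (d, d + half)


def _check_branch(branch: str) -> str:
    if branch not in BRANCHES:
        raise InvalidParameterError(f"unknown branch label {branch!r}; expected one of {BRANCHES}")
    return branch


def curvature_ratio(spec: BifurcationSpec) -> float:
    """Vessel radius / radius of curvature, (d_pmb/2) / sphere_radius."""
    if spec.sphere_radius <= 0:
        raise InvalidParameterError("sphere_radius must be positive")
    return (spec.d_pmb / 2.0) / spec.sphere_radius


# ---------------------------------------------------------------------------
# analytic branch curves on the sphere


class _Branch:
    """Great-circle arc of one branch, parametrized by arc length (mm).

    For the PMB the parameter runs from the inlet (s = 0) to the carina; for
    the daughters it runs from the carina outward.  ``carina_tangent`` is the
    unit flow-direction tangent at the carina.
    """

    def __init__(self, spec: BifurcationSpec, label: str,
                 carina: np.ndarray, carina_tangent: np.ndarray):
        self.spec = spec
        self.label = _check_branch(label)
        self.R = spec.sphere_radius
        self.C = np.asarray(carina, dtype=float)
        self.t0 = np.asarray(carina_tangent, dtype=float)
        self.length = spec.branch_length(label)
        if self.length >= np.pi * self.R:
            raise ConstructionError(
                f"{label} arc ({self.length:.1f} mm) wraps around the sphere")
        self.nominal = spec.nominal_diameter(label)
        self.pct = spec.stenosis_pct(label)
        self.window = spec.lesion_window(label)

    def _arc_from_carina(self, s):
        s = np.asarray(s, dtype=float)
        if self.label == "PMB":
            return -(self.length - s)  # upstream of the carina
        return s

    def position(self, s):
        a = self._arc_from_carina(s) / self.R
        a = np.atleast_1d(a)
        p = np.cos(a)[:, None] * self.C + (self.R * np.sin(a))[:, None] * self.t0
        return p if p.shape[0] > 1 else p[0]

    def tangent(self, s):
        a = self._arc_from_carina(s) / self.R
        a = np.atleast_1d(a)
        t = (-np.sin(a) / self.R)[:, None] * self.C + np.cos(a)[:, None] * self.t0
        return t if t.shape[0] > 1 else t[0]

    def radial(self, s):
        p = np.atleast_2d(self.position(s))
        r = p / np.linalg.norm(p, axis=1, keepdims=True)
        return r if r.shape[0] > 1 else r[0]

    # -- lesion profile -----------------------------------------------------
    def profile_weight(self, s):
        """Raised-cosine lesion shape in [0, 1]; C1-continuous, 1 at the throat."""
        s = np.asarray(s, dtype=float)
        w0, w1 = self.window
        u = np.clip((s - w0) / (w1 - w0), 0.0, 1.0)
        w = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
        return np.where((s >= w0) & (s <= w1), w, 0.0)

    def effective_diameter(self, s):
        return self.nominal * (1.0 - self.pct / 100.0 * self.profile_weight(s))

    def offset_magnitude(self, s):
        """Lumen-center displacement toward the sphere center (eccentric plaque)."""
        return 0.5 * (self.nominal - self.effective_diameter(s))

    def lumen_center(self, s):
        p = np.atleast_2d(self.position(s))
        n = np.atleast_2d(self.radial(s))
        off = np.atleast_1d(self.offset_magnitude(s))
        c = p - off[:, None] * n
        return c if c.shape[0] > 1 else c[0]

    @property
    def throat_s(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


def _carina_frame(spec: BifurcationSpec) -> dict[str, _Branch]:
    """Place the carina at (0, 0, R) and lay out the three departure tangents
    in the sphere's tangent plane there."""
    if spec.alpha_deg >= spec.beta_deg:
        raise ConstructionError(
            "distal angle alpha must be smaller than the main-branch angle beta "
            f"(got alpha={spec.alpha_deg}, beta={spec.beta_deg})")
    R = spec.sphere_radius
    C = np.array([0.0, 0.0, R])
    t_in = np.array([1.0, 0.0, 0.0])      # PMB flow direction at the carina
    up = -t_in                            # upstream PMB axis
    b = np.deg2rad(spec.beta_deg)
    t_dmb = np.cos(b) * up + np.sin(b) * np.array([0.0, 1.0, 0.0])
    a = np.deg2rad(spec.alpha_deg)
    # SB rotated by -alpha from the DMB (opposite side of the main-vessel bend)
    t_sb = np.array([np.cos(a) * t_dmb[0] + np.sin(a) * t_dmb[1],
                     np.cos(a) * t_dmb[1] - np.sin(a) * t_dmb[0], 0.0])
    return {"PMB": _Branch(spec, "PMB", C, t_in),
            "DMB": _Branch(spec, "DMB", C, t_dmb),
            "SB": _Branch(spec, "SB", C, t_sb)}


# ---------------------------------------------------------------------------
# centerlines


@dataclass
class Centerline:
    """Sampled centerline of one branch.

    Positions lie exactly on the construction sphere; tangents are unit
    vectors; arc length is strictly increasing (from the inlet for the PMB,
    from the carina for the daughters).  ``diameters`` holds the local
    effective (stenosed) lumen diameter.
    """

    label: str
    positions: np.ndarray
    tangents: np.ndarray
    diameters: np.ndarray
    arc_length: np.ndarray
    nominal_diameter: float
    lesion_window: tuple[float, float]
    sphere_radius: float
    spec: BifurcationSpec = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.arc_length)

    def position_at(self, s: float) -> np.ndarray:
        return _branch_of(self.spec, self.label).position(s)

    def tangent_at(self, s: float) -> np.ndarray:
        return _branch_of(self.spec, self.label).tangent(s)

    def to_csv(self) -> str:
        """CSV export: x, y, z, arc_length, diameter (mm)."""
        lines = ["x_mm,y_mm,z_mm,arc_length_mm,diameter_mm"]
        for p, s, d in zip(self.positions, self.arc_length, self.diameters):
            lines.append(f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{s:.6f},{d:.6f}")
        return "\n".join(lines) + "\n"


def _branch_of(spec: BifurcationSpec, label: str) -> _Branch:
    return _carina_frame(spec)[_check_branch(label)]


def build_centerlines(spec: BifurcationSpec, ds: float = 0.1) -> dict[str, Centerline]:
    """Construct the PMB/DMB/SB centerlines meeting at the carina.

    All sample points lie on the sphere of radius ``spec.sphere_radius``; the
    measured angle between the DMB and SB departure tangents equals
    ``alpha_deg`` and the angle between the upstream PMB axis and the DMB
    departure tangent equals ``beta_deg`` by construction.
    """
    branches = _carina_frame(spec)
    out: dict[str, Centerline] = {}
    for label, br in branches.items():
        n = max(int(np.ceil(br.length / ds)) + 1, 8)
        s = np.linspace(0.0, br.length, n)
        out[label] = Centerline(
            label=label,
            positions=np.atleast_2d(br.position(s)),
            tangents=np.atleast_2d(br.tangent(s)),
            diameters=np.atleast_1d(br.effective_diameter(s)),
            arc_length=s,
            nominal_diameter=br.nominal,
            lesion_window=br.window,
            sphere_radius=spec.sphere_radius,
            spec=spec,
        )
    return out


def measured_angles(centerlines: dict[str, Centerline]) -> tuple[float, float]:
    """(alpha, beta) in degrees measured from sampled centerline tangents.

    alpha: between DMB and SB departure tangents at the carina.
    beta: between the upstream-pointing PMB axis and the DMB departure tangent.
    """
    t_arr = centerlines["PMB"].tangents[-1]
    t_dmb = centerlines["DMB"].tangents[0]
    t_sb = centerlines["SB"].tangents[0]

    def ang(u, v):
        c = np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
        return float(np.degrees(np.arccos(c)))

    return ang(t_dmb, t_sb), ang(-t_arr, t_dmb)


def stenosis_profile(spec: BifurcationSpec, branch: str, s) -> tuple[float, np.ndarray]:
    """Effective lumen diameter and eccentric center offset at arc length ``s``.

    Outside the lesion window the diameter equals the branch nominal diameter
    and the offset is zero.  At the throat the diameter is
    ``nominal * (1 - pct/100)`` and the lumen center is displaced toward the
    sphere center by half the lost diameter, so the outer wall stays fixed.
    """
    br = _branch_of(spec, branch)
    if np.isscalar(s):
        if not (0.0 <= s <= br.length):
            raise InvalidParameterError(
                f"arc length {s} outside branch extent [0, {br.length:.2f}]")
        d = float(br.effective_diameter(s))
        off = -float(br.offset_magnitude(s)) * np.asarray(br.radial(s))
        return d, off
    s = np.asarray(s, dtype=float)
    d = br.effective_diameter(s)
    off = -br.offset_magnitude(s)[:, None] * np.atleast_2d(br.radial(s))
    return d, off


# ---------------------------------------------------------------------------
# lumen surface


@dataclass
class LumenMesh:
    """Watertight triangulated lumen surface with labelled inlet/outlet caps."""

    vertices: np.ndarray
    triangles: np.ndarray
    cap_labels: dict[str, np.ndarray]
    spec: BifurcationSpec = field(repr=False, default=None)
    grid_spacing: float = 0.0

    _trimesh = None

    def to_trimesh(self):
        import trimesh

        if self._trimesh is None:
            object.__setattr__(self, "_trimesh",
                               trimesh.Trimesh(self.vertices, self.triangles, process=False))
        return self._trimesh

    @property
    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def triangle_areas(self) -> np.ndarray:
        return self.to_trimesh().area_faces

    def export_stl(self, path: str) -> None:
        self.to_trimesh().export(path)


def tessellate(spec: BifurcationSpec, resolution: int = 64) -> LumenMesh:
    """Triangulate the bifurcation lumen surface.

    ``resolution`` is the target number of samples around the reference (PMB)
    circumference; the marching-cubes grid spacing is
    ``pi * d_pmb / resolution``.  Raises :class:`TessellationError` if the
    resulting surface is not a single watertight body.
    """
    from skimage.measure import marching_cubes

    if resolution < 8:
        raise InvalidParameterError("resolution must be >= 8")
    h = np.pi * spec.d_pmb / resolution
    branches = _carina_frame(spec)

    # dense swept-sphere samples per branch
    samples = {}
    for label, br in branches.items():
        ds = min(h / 2.0, 0.25)
        s = np.linspace(0.0, br.length, int(np.ceil(br.length / ds)) + 1)
        centers = np.atleast_2d(br.lumen_center(s))
        radii = 0.5 * br.effective_diameter(s)
        samples[label] = (centers, radii)

    all_centers = np.vstack([c for c, _ in samples.values()])
    rmax = max(float(r.max()) for _, r in samples.values())
    margin = rmax + 6.0 * h
    lo = all_centers.min(axis=0) - margin
    hi = all_centers.max(axis=0) + margin
    shape = np.ceil((hi - lo) / h).astype(int) + 1

    f = np.full(shape, 2.0 * h, dtype=np.float32)
    mask = np.zeros(shape, dtype=bool)
    for label, (centers, radii) in samples.items():
        stride = max(1, int(np.floor(h / min(h / 2.0, 0.25))))
        for c, r in zip(centers[::stride], radii[::stride]):
            b = r + 5.0 * h
            i0 = np.maximum(np.floor((c - b - lo) / h).astype(int), 0)
            i1 = np.minimum(np.ceil((c + b - lo) / h).astype(int) + 1, shape)
            mask[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = True

    idx = np.argwhere(mask)
    pts = lo + idx * h

    from scipy.spatial import cKDTree

    dist = np.full(len(pts), np.inf)
    for label, (centers, radii) in samples.items():
        tree = cKDTree(centers)
        d, j = tree.query(pts, workers=-1)
        dist = np.minimum(dist, d - radii[j])

    # flat end caps: gated half-space cuts at the branch end cross-sections
    caps = {"inlet": ("PMB", 0.0, -1.0),
            "outlet_dmb": ("DMB", None, +1.0),
            "outlet_sb": ("SB", None, +1.0)}
    cap_planes = {}
    for name, (label, s_end, sign) in caps.items():
        br = branches[label]
        s_end = br.length if s_end is None else s_end
        p = np.asarray(br.position(s_end))
        n = sign * np.asarray(br.tangent(s_end))
        r_end = 0.5 * br.effective_diameter(s_end)
        cap_planes[name] = (p, n, float(r_end))
        gate = 2.0 * r_end + 6.0 * h
        sel = np.linalg.norm(pts - p, axis=1) < gate
        plane_val = (pts[sel] - p) @ n
        dist[sel] = np.maximum(dist[sel], plane_val)

    f[tuple(idx.T)] = dist
    # nudge exact zeros off the iso-level so marching cubes stays non-degenerate
    f[f == 0.0] = 1e-9

    verts, faces, _, _ = marching_cubes(np.ascontiguousarray(f), level=0.0,
                                        spacing=(h, h, h), allow_degenerate=False)
    verts = verts + lo

    import trimesh

    tm = trimesh.Trimesh(verts, faces, process=False)
    if tm.volume < 0:
        tm.invert()
    if tm.body_count != 1:
        raise TessellationError(
            f"surface split into {tm.body_count} bodies; check angles/stenoses "
            "for self-contact of the branches")
    if not tm.is_watertight:
        raise TessellationError("triangulated lumen surface is not watertight")

    centroids = tm.triangles_center
    cap_labels = {}
    for name, (p, n, r_end) in cap_planes.items():
        on_plane = np.abs((centroids - p) @ n) < 0.75 * h
        near = np.linalg.norm(centroids - p, axis=1) < 2.0 * r_end + 6.0 * h
        cap_labels[name] = np.flatnonzero(on_plane & near)
        if len(cap_labels[name]) == 0:
            raise TessellationError(f"no triangles found for cap {name!r}")

    mesh = LumenMesh(vertices=tm.vertices.view(np.ndarray).copy(),
                     triangles=tm.faces.view(np.ndarray).copy(),
                     cap_labels=cap_labels, spec=spec, grid_spacing=h)
    object.__setattr__(mesh, "_trimesh", tm)
    return mesh


def _ortho_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, ref)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(normal, e1)


def _assemble_loops(segments2d: np.ndarray, tol: float = 1e-7) -> list[np.ndarray]:
    """Chain 2D line segments (n, 2, 2) into closed loops by endpoint matching."""
    def key(p):
        return (round(p[0] / tol), round(p[1] / tol))

    adjacency: dict = {}
    for i, seg in enumerate(segments2d):
        if np.linalg.norm(seg[1] - seg[0]) < tol:
            continue
        for end in (0, 1):
            adjacency.setdefault(key(seg[end]), []).append((i, end))

    used = np.zeros(len(segments2d), dtype=bool)
    loops = []
    for i in range(len(segments2d)):
        if used[i]:
            continue
        loop = [segments2d[i][0], segments2d[i][1]]
        used[i] = True
        while True:
            k = key(loop[-1])
            nxt = [(j, e) for j, e in adjacency.get(k, []) if not used[j]]
            if not nxt:
                break
            j, e = nxt[0]
            used[j] = True
            loop.append(segments2d[j][1 - e])
            if key(loop[-1]) == key(loop[0]):
                break
        if len(loop) >= 4 and key(loop[-1]) == key(loop[0]):
            loops.append(np.asarray(loop[:-1]))
    return loops


def _section_equivalent_diameter(tmesh, origin: np.ndarray, normal: np.ndarray) -> float | None:
    """Equivalent diameter 2*sqrt(A/pi) of the mesh cross-section containing
    ``origin``; None if the plane misses the mesh."""
    from trimesh.intersections import mesh_plane

    segs = mesh_plane(tmesh, plane_normal=normal, plane_origin=origin)
    if len(segs) == 0:
        return None
    e1, e2 = _ortho_basis(np.asarray(normal, dtype=float))
    rel = segs - origin
    segs2d = np.stack([rel @ e1, rel @ e2], axis=-1)
    loops = _assemble_loops(segs2d)
    if not loops:
        return None

    from shapely.geometry import Point, Polygon

    pt = Point(0.0, 0.0)
    best, best_d = None, np.inf
    for loop in loops:
        poly = Polygon(loop)
        if not poly.is_valid:
            poly = poly.buffer(0)
        if poly.contains(pt):
            best = poly
            break
        d = poly.exterior.distance(pt) if poly.geom_type == "Polygon" else poly.distance(pt)
        if d < best_d:
            best, best_d = poly, d
    return 2.0 * np.sqrt(best.area / np.pi)


def measure_stenosis(mesh: LumenMesh, branch: str, n_stations: int = 25) -> float:
    """Percent diameter stenosis measured on the tessellated surface.

    Slices the mesh along the branch's lesion window, takes the minimum
    equivalent diameter (2*sqrt(area/pi)) and reports
    100 * (1 - min diameter / nominal diameter).
    """
    br = _branch_of(mesh.spec, branch)
    tm = mesh.to_trimesh()
    w0, w1 = br.window
    stations = np.linspace(w0, w1, n_stations)
    d_min = np.inf
    for s in stations:
        origin = np.asarray(br.lumen_center(s))
        normal = np.asarray(br.tangent(s))
        d = _section_equivalent_diameter(tm, origin, normal)
        if d is not None:
            d_min = min(d_min, d)
    if not np.isfinite(d_min):
        raise TessellationError(f"no cross-sections found in {branch} lesion window")
    return 100.0 * (1.0 - d_min / br.nominal)


def measure_cap_diameter(mesh: LumenMesh, cap: str = "inlet", inset: float | None = None) -> float:
    """Equivalent diameter of a cap cross-section, measured slightly inside
    the cap plane to avoid the cap triangles themselves."""
    spec = mesh.spec
    label = {"inlet": "PMB", "outlet_dmb": "DMB", "outlet_sb": "SB"}[cap]
    br = _branch_of(spec, label)
    inset = 2.0 * mesh.grid_spacing if inset is None else inset
    s = inset if cap == "inlet" else br.length - inset
    d = _section_equivalent_diameter(mesh.to_trimesh(),
                                     np.asarray(br.lumen_center(s)),
                                     np.asarray(br.tangent(s)))
    if d is None:
        raise TessellationError(f"no cross-section at cap {cap!r}")
    return d
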