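import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bifurcfr as b

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")

#: tessellation resolution used for quantitative self-measurement; chosen so
#: the narrowest (80 %) side-branch throat is resolved by ~20 circumferential
#: vertices (see docs/methods.md)
MEASURE_RESOLUTION = 104


@pytest.fixture(scope="session")
def default_spec():
    return b.BifurcationSpec()


@pytest.fixture(scope="session")
def grid_geometry_measurements():
    """Tessellate the nine distinct lumen geometries of the 27-case grid
    (3 distal angles x 3 SB stenoses; flow split does not change the lumen)
    and self-measure stenosis severities and bifurcation angles."""
    out = {}
    for alpha in b.hemodynamics.STUDY_ANGLES_DEG:
        for sb in b.hemodynamics.STUDY_SB_STENOSES_PCT:
            spec = b.BifurcationSpec(alpha_deg=alpha, stenosis_sb_pct=sb)
            mesh = b.tessellate(spec, resolution=MEASURE_RESOLUTION)
            cls = b.build_centerlines(spec)
            meas_alpha, meas_beta = b.measured_angles(cls)
            sphere_dev = max(
                np.abs(np.linalg.norm(cl.positions, axis=1) - spec.sphere_radius).max()
                for cl in cls.values())
            out[(alpha, sb)] = {
                "spec": spec,
                "watertight": mesh.is_watertight,
                "min_face_area": float(mesh.triangle_areas().min()),
                "alpha": meas_alpha,
                "beta": meas_beta,
                "sphere_dev": float(sphere_dev),
                "stenosis": {br: b.measure_stenosis(mesh, br)
                             for br in ("PMB", "DMB", "SB")},
                "inlet_diameter": b.measure_cap_diameter(mesh),
            }
    return out


@pytest.fixture(scope="session")
def jet_field_extreme():
    """Stenotic fixture field for the most severe case (80 % SB, 70 deg,
    45 % SB flow) with the published pressure drops imposed."""
    spec = b.BifurcationSpec(alpha_deg=70.0, stenosis_sb_pct=80.0)
    flow = b.FlowConditions(split_dmb=0.55, split_sb=0.45)
    field = b.stenotic_jet_field(spec, flow, dp_mb=12.60, dp_sb=85.98, mesh_density=16)
    return spec, flow, field
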