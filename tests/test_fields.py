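"""Field post-processing: vorticity reconstruction, helicity descriptors,
section probes, pressure drops and FFR."""

import numpy as np
import pytest

import bifurcfr as b
from bifurcfr.fields import SectionProbe, _slice_tets, section_flux
from bifurcfr.synthetic import AnalyticFieldSpec, _cylinder_lattice, _tet_volumes


def _cylinder_field(velocity_fn, pressure_fn=None, density=12, radius=1.65, length=10.0):
    spec = AnalyticFieldSpec(kind="poiseuille", radius=radius, length=length,
                             mesh_density=density)
    pts, tets = _cylinder_lattice(spec)
    vel = velocity_fn(pts)
    p = np.full(len(pts), 100.0) if pressure_fn is None else pressure_fn(pts)
    return b.FlowField(points=pts, velocity=vel, pressure=p, cells=tets,
                       cell_volumes=_tet_volumes(pts, tets))


def _mid_probe(field, z, normal=(0.0, 0.0, 1.0)):
    origin = np.array([0.0, 0.0, z])
    normal = np.asarray(normal)
    sl = _slice_tets(field, origin, normal)
    assert sl is not None
    return SectionProbe(branch="test", location=z, plane_origin=origin,
                        plane_normal=normal, positions=sl[0], pressure=sl[1],
                        velocity=sl[2], weights=sl[3])


class TestVorticity:
    def test_exact_on_affine_fields(self):
        G = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6], [0.7, 0.8, 0.9]])
        field = _cylinder_field(lambda p: (p * 1e-3) @ G + np.array([1.0, -2.0, 0.5]))
        omega, flagged = b.vorticity(field)
        expected = np.array([G[1, 2] - G[2, 1], G[2, 0] - G[0, 2], G[0, 1] - G[1, 0]])
        assert np.abs(omega - expected).max() < 1e-10 * np.abs(expected).max()
        assert not flagged.any()

    def test_rigid_rotation(self):
        # v = (-y, x, 0) (SI) has omega = (0, 0, 2) everywhere
        field = _cylinder_field(
            lambda p: np.column_stack([-p[:, 1], p[:, 0], np.zeros(len(p))]) * 1e-3)
        omega, _ = b.vorticity(field)
        assert np.allclose(omega, [0.0, 0.0, 2.0], atol=1e-9)

    def test_uniform_flow_is_irrotational(self):
        field = _cylinder_field(lambda p: np.tile([0.0, 0.0, 0.3], (len(p), 1)))
        omega, _ = b.vorticity(field)
        assert np.abs(omega).max() < 1e-12

    def test_poiseuille_magnitude(self):
        # |omega| = 2 v_max r / R^2 for a parabolic profile; check away from
        # the wall where the one-sided neighbourhoods degrade accuracy
        spec = AnalyticFieldSpec(kind="poiseuille", radius=1.65, length=8.0,
                                 mesh_density=24)
        field = b.poiseuille_field(spec)
        omega, _ = b.vorticity(field)
        r = np.linalg.norm(field.points[:, :2], axis=1) * 1e-3
        R = 1.65e-3
        v_max = field.velocity[:, 2].max()
        expected = 2.0 * v_max * r / R ** 2
        interior = (r > 0.2 * R) & (r < 0.8 * R) & \
            (field.points[:, 2] > 2.0) & (field.points[:, 2] < 6.0)
        err = np.abs(np.linalg.norm(omega[interior], axis=1) - expected[interior])
        assert np.median(err / expected[interior]) < 0.02


class TestLocalNormalizedHelicity:
    def test_poiseuille_is_zero(self):
        field = b.poiseuille_field(AnalyticFieldSpec(kind="poiseuille", mesh_density=12))
        lnh = b.local_normalized_helicity(field)
        assert np.abs(lnh).max() < 1e-9

    def test_helical_closed_form(self):
        spec = AnalyticFieldSpec(kind="helical", omega=200.0, mesh_density=16)
        field = b.helical_field(spec)
        lnh = b.local_normalized_helicity(field)
        r = np.linalg.norm(field.points[:, :2], axis=1)
        exact = b.helical_lnh_exact(spec, r)
        assert np.abs(lnh - exact).max() < 1e-3  # 0.1 % of the unit-bounded LNH

    def test_on_axis_alignment(self):
        spec = AnalyticFieldSpec(kind="helical", omega=200.0, mesh_density=16)
        field = b.helical_field(spec)
        on_axis = np.linalg.norm(field.points[:, :2], axis=1) < 1e-9
        lnh = b.local_normalized_helicity(field)
        assert np.allclose(lnh[on_axis], 1.0, atol=1e-9)

    def test_bounded(self, jet_field_extreme):
        _, _, field = jet_field_extreme
        lnh = b.local_normalized_helicity(field)
        assert np.all(lnh >= -1.0) and np.all(lnh <= 1.0)

    def test_sign_flips_under_reflection(self):
        spec = AnalyticFieldSpec(kind="helical", omega=200.0, mesh_density=12)
        field = b.helical_field(spec)
        mirror = np.diag([1.0, -1.0, 1.0])
        reflected = b.FlowField(points=field.points @ mirror,
                                velocity=field.velocity @ mirror,
                                pressure=field.pressure, cells=field.cells,
                                cell_volumes=field.cell_volumes)
        lnh = b.local_normalized_helicity(field)
        lnh_r = b.local_normalized_helicity(reflected)
        assert np.allclose(lnh_r, -lnh, atol=1e-9)


class TestHelicityIntensity:
    def test_quiescent_field(self):
        field = _cylinder_field(lambda p: np.zeros((len(p), 3)))
        assert b.helicity_intensity(field) == 0.0

    def test_helical_closed_form(self):
        # v = (-Om y, Om x, W): |v.w| = 2 Om W everywhere
        spec = AnalyticFieldSpec(kind="helical", omega=150.0, mesh_density=16)
        field = b.helical_field(spec)
        W = field.velocity[0, 2]
        assert b.helicity_intensity(field) == pytest.approx(2 * 150.0 * W, rel=1e-3)

    def test_rotation_invariance(self):
        from scipy.spatial.transform import Rotation

        spec = AnalyticFieldSpec(kind="helical", omega=150.0, mesh_density=12)
        field = b.helical_field(spec)
        Q = Rotation.from_rotvec([0.4, -0.3, 1.1]).as_matrix()
        rotated = b.FlowField(points=field.points @ Q.T, velocity=field.velocity @ Q.T,
                              pressure=field.pressure, cells=field.cells,
                              cell_volumes=field.cell_volumes)
        assert b.helicity_intensity(rotated) == pytest.approx(
            b.helicity_intensity(field), rel=1e-9)

    def test_quadratic_velocity_scaling(self):
        spec = AnalyticFieldSpec(kind="helical", omega=150.0, mesh_density=12)
        field = b.helical_field(spec)
        scaled = b.FlowField(points=field.points, velocity=3.0 * field.velocity,
                             pressure=field.pressure, cells=field.cells,
                             cell_volumes=field.cell_volumes)
        assert b.helicity_intensity(scaled) == pytest.approx(
            9.0 * b.helicity_intensity(field), rel=1e-9)


class TestSectionProbes:
    def test_constant_pressure_mean(self):
        field = _cylinder_field(lambda p: np.tile([0.0, 0.0, 0.2], (len(p), 1)))
        probe = _mid_probe(field, 5.03)
        assert b.mean_pressure(probe) == pytest.approx(100.0, abs=1e-9)

    def test_linear_pressure_field_gives_centroid_value(self):
        # p = 90 + 4x + 2y: the area-weighted mean over the centered disc
        # section equals the centroid value 90
        field = _cylinder_field(lambda p: np.tile([0.0, 0.0, 0.2], (len(p), 1)),
                                pressure_fn=lambda p: 90.0 + 4.0 * p[:, 0] + 2.0 * p[:, 1],
                                density=16)
        probe = _mid_probe(field, 5.03)
        assert b.mean_pressure(probe) == pytest.approx(90.0, abs=1e-3)

    def test_weights_sum_to_section_area(self):
        field = _cylinder_field(lambda p: np.tile([0.0, 0.0, 0.2], (len(p), 1)),
                                density=24)
        probe = _mid_probe(field, 5.03)
        assert probe.area == pytest.approx(np.pi * 1.65 ** 2, rel=0.005)

    def test_pressure_drop_arithmetic(self):
        field = _cylinder_field(lambda p: np.tile([0.0, 0.0, 0.2], (len(p), 1)),
                                pressure_fn=lambda p: np.full(len(p), 77.47))
        probe = _mid_probe(field, 5.03)
        assert b.pressure_drop(100.0, probe) == pytest.approx(22.53, abs=1e-9)
        assert b.pressure_drop(77.47, probe) == pytest.approx(0.0, abs=1e-9)

    def test_probe_outside_domain_rejected(self, jet_field_extreme):
        spec, _, field = jet_field_extreme
        cls = b.build_centerlines(spec)
        with pytest.raises(b.ProbeError):
            b.extract_section(field, cls["SB"], offset_diameters=50.0, side="distal")


class TestFfr:
    @pytest.mark.parametrize("p_prox, p_dist, expected", [
        (100.0, 14.02, 0.140),
        (100.0, 100.0, 1.000),
        (100.0, 77.47, 0.775),
    ])
    def test_values(self, p_prox, p_dist, expected):
        assert round(b.ffr(p_prox, p_dist), 3) == expected

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(b.InvalidParameterError):
            b.ffr(0.0, 50.0)


class TestProbePipelineOnFixtureField:
    def test_prescribed_drops_recovered(self, jet_field_extreme):
        # the imposed dP of the synthetic stenotic field is reproduced by the
        # probe/mean-pressure pipeline well within 0.5 %
        spec, _, field = jet_field_extreme
        cls = b.build_centerlines(spec)
        p_prox = b.mean_pressure(b.extract_section(field, cls["PMB"], 1.0, "proximal"))
        probe_sb = b.extract_section(field, cls["SB"], 1.0, "distal")
        probe_mb = b.extract_section(field, cls["DMB"], 1.0, "distal")
        assert p_prox == pytest.approx(100.0, abs=1e-6)
        assert b.pressure_drop(p_prox, probe_sb) == pytest.approx(85.98, rel=0.005)
        assert b.pressure_drop(p_prox, probe_mb) == pytest.approx(12.60, rel=0.005)
        assert b.ffr(p_prox, b.mean_pressure(probe_sb)) == pytest.approx(0.140, abs=0.001)

    def test_mass_conservation_across_junction(self, jet_field_extreme):
        spec, flow, field = jet_field_extreme
        cls = b.build_centerlines(spec)
        f_in = section_flux(b.extract_section(field, cls["PMB"], 1.0, "proximal"))
        f_dmb = section_flux(b.extract_section(field, cls["DMB"], 1.0, "distal"))
        f_sb = section_flux(b.extract_section(field, cls["SB"], 1.0, "distal"))
        assert abs(f_in - f_dmb - f_sb) / f_in < 0.005
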