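"""Geometry builder: Finet diameters, spherical centerlines, eccentric
raised-cosine stenoses, and watertight surface tessellation."""

import numpy as np
import pytest

import bifurcfr as b
from bifurcfr.geometry import _branch_of


class TestFinetLaw:
    @pytest.mark.parametrize("d_dmb, d_sb, expected", [
        (2.77, 2.10, 3.30),     # reference daughter diameters
        (0.0, 0.0, 0.0),
        (2.0, 2.0, 2.712),
    ])
    def test_values(self, d_dmb, d_sb, expected):
        assert round(b.finet_pmb_diameter(d_dmb, d_sb), 3) == pytest.approx(expected, abs=5e-3)

    def test_negative_input_rejected(self):
        with pytest.raises(b.InvalidParameterError):
            b.finet_pmb_diameter(-1.0, 2.0)

    def test_default_spec_consistent_with_finet(self, default_spec):
        d = b.finet_pmb_diameter(default_spec.d_dmb, default_spec.d_sb)
        assert round(d, 2) == round(default_spec.d_pmb, 2)


class TestCurvatureRatio:
    def test_reference_value(self, default_spec):
        assert b.curvature_ratio(default_spec) == pytest.approx(0.0293, abs=5e-4)
        assert round(b.curvature_ratio(default_spec), 2) == 0.03

    def test_vanishes_for_flat_vessel(self):
        prev = np.inf
        for radius in (60.0, 600.0, 6000.0):
            cr = b.curvature_ratio(b.BifurcationSpec(sphere_radius=radius))
            assert 0 < cr < prev
            prev = cr


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(d_pmb=-1.0),
        dict(alpha_deg=0.0),
        dict(beta_deg=190.0),
        dict(stenosis_sb_pct=100.0),
        dict(stenosis_pmb_pct=-5.0),
        dict(pmb_length=0.0),
        dict(sphere_radius=2.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(b.InvalidParameterError):
            b.BifurcationSpec(**kwargs)

    def test_yaml_round_trip(self, default_spec):
        assert b.BifurcationSpec.from_yaml(default_spec.to_yaml()) == default_spec


class TestCenterlines:
    @pytest.mark.parametrize("alpha", [40.0, 55.0, 70.0])
    def test_measured_angles_match_spec(self, alpha):
        cls = b.build_centerlines(b.BifurcationSpec(alpha_deg=alpha))
        meas_alpha, meas_beta = b.measured_angles(cls)
        assert meas_alpha == pytest.approx(alpha, abs=0.1)
        assert meas_beta == pytest.approx(150.0, abs=0.1)

    def test_points_on_sphere_and_unit_tangents(self, default_spec):
        for cl in b.build_centerlines(default_spec).values():
            r = np.linalg.norm(cl.positions, axis=1)
            assert np.abs(r - default_spec.sphere_radius).max() < 1e-6
            assert np.abs(np.linalg.norm(cl.tangents, axis=1) - 1).max() < 1e-9
            assert np.all(np.diff(cl.arc_length) > 0)

    def test_branches_meet_at_carina(self, default_spec):
        cls = b.build_centerlines(default_spec)
        carina = cls["PMB"].positions[-1]
        assert np.allclose(cls["DMB"].positions[0], carina, atol=1e-9)
        assert np.allclose(cls["SB"].positions[0], carina, atol=1e-9)

    def test_pre_stenosis_arc_length(self, default_spec):
        # healthy PMB segment from inlet to lesion start is eight diameters
        assert default_spec.lesion_window("PMB")[0] == pytest.approx(26.4)

    def test_pathway_lesion_length_totals(self, default_spec):
        for daughter in ("DMB", "SB"):
            w_pmb = default_spec.lesion_window("PMB")
            w_d = default_spec.lesion_window(daughter)
            total = (w_pmb[1] - w_pmb[0]) + (w_d[1] - w_d[0])
            assert total == pytest.approx(default_spec.lesion_length)

    def test_infeasible_angles_rejected(self):
        with pytest.raises(b.ConstructionError):
            b.build_centerlines(b.BifurcationSpec(alpha_deg=160.0, beta_deg=150.0))


class TestStenosisProfile:
    def test_throat_diameter(self, default_spec):
        br = _branch_of(default_spec, "PMB")
        d, off = b.stenosis_profile(default_spec, "PMB", br.throat_s)
        assert d == pytest.approx(3.30 * 0.40, abs=1e-9)
        # plaque displaces the lumen center toward the sphere center by half
        # the lost diameter (outer wall fixed)
        assert np.linalg.norm(off) == pytest.approx((3.30 - d) / 2, abs=1e-9)
        radial = np.asarray(br.radial(br.throat_s))
        assert np.dot(off, radial) < 0

    def test_identity_outside_lesion(self, default_spec):
        for s in (0.5, 10.0, default_spec.lesion_window("PMB")[0] - 0.01):
            d, off = b.stenosis_profile(default_spec, "PMB", s)
            assert d == default_spec.d_pmb
            assert np.linalg.norm(off) == 0.0

    def test_zero_stenosis_is_identity_everywhere(self):
        spec = b.BifurcationSpec(stenosis_pmb_pct=0.0, stenosis_dmb_pct=0.0,
                                 stenosis_sb_pct=0.0)
        s = np.linspace(0.1, spec.branch_length("DMB") - 0.1, 50)
        d, off = b.stenosis_profile(spec, "DMB", s)
        assert np.allclose(d, spec.d_dmb)
        assert np.allclose(off, 0.0)

    def test_profile_c1_continuity(self, default_spec):
        # slope jumps of a C1 profile are bounded by |d''|_max * ds; a kink
        # would leave an O(1) jump independent of the sampling step
        br = _branch_of(default_spec, "SB")
        s = np.linspace(0.0, br.length, 4001)
        ds = s[1] - s[0]
        slope = np.gradient(br.effective_diameter(s), s)
        w = br.window[1] - br.window[0]
        dd_max = br.nominal * br.pct / 100.0 * 0.5 * (2 * np.pi / w) ** 2
        assert np.abs(np.diff(slope)).max() < 2.0 * dd_max * ds

    def test_outer_wall_fixed(self, default_spec):
        # eccentricity: center offset + effective radius == nominal radius,
        # so the wall away from the sphere center does not move
        br = _branch_of(default_spec, "PMB")
        s = np.linspace(br.window[0], br.window[1], 21)
        assert np.allclose(br.offset_magnitude(s) + 0.5 * br.effective_diameter(s),
                           0.5 * br.nominal, atol=1e-12)

    def test_unknown_branch_rejected(self, default_spec):
        with pytest.raises(b.InvalidParameterError):
            b.stenosis_profile(default_spec, "LAD", 1.0)

    def test_out_of_extent_rejected(self, default_spec):
        with pytest.raises(b.InvalidParameterError):
            b.stenosis_profile(default_spec, "SB", 1e4)


@pytest.fixture(scope="module")
def default_mesh(default_spec):
    return b.tessellate(default_spec, resolution=64)


class TestTessellation:
    def test_watertight_with_positive_areas(self, default_mesh):
        assert default_mesh.is_watertight
        assert default_mesh.triangle_areas().min() > 0

    def test_inlet_cap_diameter(self, default_mesh, default_spec):
        d = b.measure_cap_diameter(default_mesh, "inlet")
        assert d == pytest.approx(default_spec.d_pmb, rel=0.01)

    def test_caps_labelled(self, default_mesh):
        for cap in ("inlet", "outlet_dmb", "outlet_sb"):
            assert len(default_mesh.cap_labels[cap]) > 0

    def test_resolution_convergence_of_throat(self, default_spec):
        # doubling the resolution moves the measured PMB throat diameter
        # by less than 0.5 %
        d = {}
        for res in (64, 128):
            mesh = b.tessellate(default_spec, resolution=res)
            pct = b.measure_stenosis(mesh, "PMB")
            d[res] = default_spec.d_pmb * (1 - pct / 100.0)
        assert abs(d[128] - d[64]) / d[128] < 0.005

    def test_low_resolution_rejected(self, default_spec):
        with pytest.raises(b.InvalidParameterError):
            b.tessellate(default_spec, resolution=4)

    def test_stl_export(self, default_mesh, tmp_path):
        path = tmp_path / "lumen.stl"
        default_mesh.export_stl(str(path))
        assert path.stat().st_size > 0


class TestCenterlineExports:
    def test_csv_columns(self, default_spec):
        cl = b.build_centerlines(default_spec)["SB"]
        text = cl.to_csv()
        header = text.splitlines()[0].split(",")
        assert header == ["x_mm", "y_mm", "z_mm", "arc_length_mm", "diameter_mm"]
        assert len(text.splitlines()) == len(cl) + 1

    def test_vtk_polyline(self, default_spec, tmp_path):
        from bifurcfr.vtkio import write_centerline

        cl = b.build_centerlines(default_spec)["PMB"]
        path = tmp_path / "pmb.vtk"
        write_centerline(str(path), cl)
        text = path.read_text()
        assert "POLYDATA" in text and "diameter_mm" in text
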