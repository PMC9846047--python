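import numpy as np
import pytest
import trimesh

from tmstarget import (
    CPCCoordinate,
    ScalpMesh,
    coil_frame,
    coil_frames,
    cpc_forward,
    cpc_inverse,
    make_head,
    restore_placement_from_cortical_target,
    sagittal_curve,
)
from tmstarget.errors import DataError, DegenerateCoordinateError, NotReachableError
from tmstarget.synthetic import HeadSpec

from conftest import sphere_cpc_oracle


class TestScalpMesh:
    def test_coincident_nz_iz_rejected(self, unit_head):
        lm = dict(unit_head.landmarks)
        lm["IZ"] = lm["NZ"]
        with pytest.raises(DataError, match="NZ and IZ"):
            ScalpMesh(unit_head.mesh, lm)

    def test_off_surface_landmark_rejected(self, unit_head):
        lm = dict(unit_head.landmarks)
        lm["AL"] = np.array([-3.0, 0.0, 0.0])
        with pytest.raises(DataError, match="from the surface"):
            ScalpMesh(unit_head.mesh, lm)

    def test_mesh_io_round_trip(self, unit_head, tmp_path):
        unit_head.save(tmp_path / "head.ply", tmp_path / "lm.json")
        back = ScalpMesh.load(tmp_path / "head.ply", tmp_path / "lm.json")
        assert len(back.mesh.vertices) == len(unit_head.mesh.vertices)
        assert np.allclose(back.nz, unit_head.nz)


class TestSagittalCurve:
    def test_great_arc_length_on_sphere(self, unit_head):
        curve = sagittal_curve(unit_head)
        length = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
        assert abs(length - np.pi) < 2 * unit_head.mean_edge_length

    def test_endpoints_are_landmarks(self, unit_head):
        curve = unit_head.sagittal
        assert np.allclose(curve[0], unit_head.nz)
        assert np.allclose(curve[-1], unit_head.iz)

    def test_curve_stays_on_upper_surface(self, unit_head):
        assert unit_head.sagittal[1:-1, 2].min() > -1e-6


class TestCPCForward:
    def test_apex_at_center_coordinates(self, unit_head):
        p = cpc_forward(unit_head, CPCCoordinate(0.5, 0.5))
        assert np.linalg.norm(p - [0, 0, 1]) < 2 * unit_head.mean_edge_length

    def test_p_al_zero_is_al_terminus(self, unit_head):
        p = cpc_forward(unit_head, CPCCoordinate(0.5, 0.0))
        assert np.linalg.norm(p - unit_head.al) < 1e-9

    @pytest.mark.parametrize(
        "c", [(0.3, 0.7), (0.4, 0.6), (0.2, 0.2), (0.8, 0.35), (0.65, 0.5)]
    )
    def test_matches_analytic_sphere_oracle(self, unit_head, c):
        p = cpc_forward(unit_head, CPCCoordinate(*c))
        err = np.linalg.norm(p - sphere_cpc_oracle(*c))
        assert err < 2 * unit_head.mean_edge_length

    @pytest.mark.parametrize("p_nz", [0.0, 1.0])
    def test_poles_rejected(self, unit_head, p_nz):
        with pytest.raises(DegenerateCoordinateError):
            cpc_forward(unit_head, CPCCoordinate(p_nz, 0.3))

    def test_refinement_halves_oracle_error(self, coarse_head, unit_head):
        coords = [(0.3, 0.7), (0.4, 0.4), (0.6, 0.55), (0.25, 0.3), (0.7, 0.65)]
        def mean_err(head):
            return np.mean(
                [
                    np.linalg.norm(
                        cpc_forward(head, CPCCoordinate(*c)) - sphere_cpc_oracle(*c)
                    )
                    for c in coords
                ]
            )
        assert mean_err(unit_head) <= 0.5 * mean_err(coarse_head)


class TestCPCInverse:
    @pytest.mark.parametrize("c", [(0.4, 0.6), (0.3, 0.3), (0.7, 0.45)])
    def test_round_trip(self, unit_head, c):
        back = cpc_inverse(unit_head, cpc_forward(unit_head, CPCCoordinate(*c)))
        assert back.p_nz == pytest.approx(c[0], abs=0.01)
        assert back.p_al == pytest.approx(c[1], abs=0.01)

    def test_landmark_anchoring(self, unit_head):
        assert cpc_inverse(unit_head, unit_head.nz).p_nz == 0.0
        assert cpc_inverse(unit_head, unit_head.iz).p_nz == 1.0
        assert cpc_inverse(unit_head, unit_head.al).p_al == pytest.approx(0.0, abs=0.01)
        assert cpc_inverse(unit_head, unit_head.ar).p_al == pytest.approx(1.0, abs=0.01)

    def test_off_surface_point_rejected(self, unit_head):
        with pytest.raises(DataError, match="off the surface"):
            cpc_inverse(unit_head, np.array([0.0, 0.0, 2.0]))

    def test_dense_round_trip_on_upper_surface(self, unit_head):
        tol = 2 * unit_head.mean_edge_length
        for p_nz in np.linspace(0.15, 0.85, 5):
            for p_al in np.linspace(0.15, 0.85, 5):
                p = cpc_forward(unit_head, CPCCoordinate(p_nz, p_al))
                back = cpc_forward(unit_head, cpc_inverse(unit_head, p))
                assert np.linalg.norm(back - p) < tol


class TestCoilFrame:
    def test_apex_zero_points_backward(self, unit_head):
        fr = coil_frame(unit_head, CPCCoordinate(0.5, 0.5), 0.0)
        chord = unit_head.iz - fr.center
        tangential = chord - (chord @ fr.normal) * fr.normal
        assert fr.handle_dir @ tangential > 0

    def test_half_turn_negates_zero_direction(self, unit_head):
        fr = coil_frame(unit_head, CPCCoordinate(0.5, 0.5), 180.0)
        assert np.allclose(fr.handle_dir, -fr.zero_dir, atol=1e-9)

    def test_opposite_quarter_turns_are_negatives(self, unit_head):
        f1 = coil_frame(unit_head, CPCCoordinate(0.4, 0.6), 90.0)
        f2 = coil_frame(unit_head, CPCCoordinate(0.4, 0.6), -90.0)
        assert np.allclose(f1.handle_dir, -f2.handle_dir, atol=1e-9)
        assert abs(f1.handle_dir @ f1.zero_dir) < 1e-9

    def test_rotation_matrix_oracle_in_tangent_plane(self, unit_head):
        c = CPCCoordinate(0.35, 0.55)
        base = coil_frame(unit_head, c, 0.0)
        for theta in (-120.0, -45.0, 30.0, 150.0):
            fr = coil_frame(unit_head, c, theta)
            # 2D rotation oracle in the (zero_dir, normal x zero_dir) basis
            e2 = np.cross(base.normal, base.zero_dir)
            t = np.deg2rad(theta)
            expected = np.cos(t) * base.zero_dir + np.sin(t) * e2
            assert np.allclose(fr.handle_dir, expected, atol=1e-9)

    @pytest.mark.parametrize("c", [(0.3, 0.3), (0.5, 0.5), (0.7, 0.6)])
    def test_orthonormality(self, unit_head, c):
        fr = coil_frame(unit_head, CPCCoordinate(*c), -45.0)
        for v in (fr.normal, fr.zero_dir, fr.handle_dir):
            assert abs(np.linalg.norm(v) - 1.0) < 1e-9
        assert abs(fr.normal @ fr.zero_dir) < 1e-9
        assert abs(fr.normal @ fr.handle_dir) < 1e-9

    def test_theta_periodicity(self, unit_head):
        c = CPCCoordinate(0.45, 0.55)
        a = coil_frame(unit_head, c, 180.0).handle_dir
        b = coil_frame(unit_head, c, -180.0 + 1e-9).handle_dir
        assert np.allclose(a, b, atol=1e-6)

    def test_batched_frames_match_single_calls(self, unit_head):
        c = CPCCoordinate(0.6, 0.4)
        thetas = [0.0, -90.0, 135.0]
        batched = coil_frames(unit_head, c, thetas)
        for theta, fr in zip(thetas, batched):
            single = coil_frame(unit_head, c, theta)
            assert np.allclose(fr.handle_dir, single.handle_dir, atol=1e-12)

    def test_invalid_theta_rejected(self, unit_head):
        with pytest.raises(DataError, match="theta"):
            coil_frame(unit_head, CPCCoordinate(0.5, 0.5), -180.0)


class TestRestorePlacement:
    def test_target_under_apex_restores_center(self, unit_head):
        cpc = restore_placement_from_cortical_target(unit_head, np.array([0, 0, 0.88]))
        assert cpc.p_nz == pytest.approx(0.5, abs=0.02)
        assert cpc.p_al == pytest.approx(0.5, abs=0.02)

    def test_target_outside_head_rejected(self, unit_head):
        with pytest.raises(NotReachableError):
            restore_placement_from_cortical_target(unit_head, np.array([0, 0, 2.0]))

    def test_center_tie_break_is_deterministic(self, unit_head):
        a = restore_placement_from_cortical_target(unit_head, np.zeros(3))
        b = restore_placement_from_cortical_target(unit_head, np.zeros(3))
        assert (a.p_nz, a.p_al) == (b.p_nz, b.p_al)

    def test_oblique_target_restores_its_radial_point(self, head85):
        # on a sphere the inward normal is radial, so the best scalp point for
        # a target at 0.8R along direction d is the surface point along d
        d = np.array([0.3, -0.5, 0.81])
        d /= np.linalg.norm(d)
        cpc = restore_placement_from_cortical_target(head85, 0.8 * 85.0 * d)
        restored = cpc_forward(head85, cpc)
        assert np.linalg.norm(restored - 85.0 * d) < 3 * head85.mean_edge_length
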