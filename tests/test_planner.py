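"""Osteotomy planner: centerline, plane cuts, objective, exhaustive search."""

import numpy as np
import pytest

from osteoplan.geometry import RigidTransform, mesh_volume
from osteoplan.planner import (
    BoneFrame,
    OsteotomyPlane,
    SearchGrid,
    centerline,
    compare_planes,
    cut_contour,
    cut_with_plane,
    exhaustive_search,
    objective,
    reconstruct,
    secondary_cut,
)
from osteoplan.registration import initial_align, register_joint_ends
from osteoplan.synthetic import SyntheticCaseSpec, apply_wedge, make_healthy_bone

from conftest import random_rigid


@pytest.fixture(scope="module")
def bone():
    mesh, _ = make_healthy_bone(SyntheticCaseSpec(seed=11))
    return mesh


@pytest.fixture(scope="module")
def frame(bone):
    return BoneFrame.from_mesh(bone)


def mid_plane(bone, frame, tilt_a=0.0, tilt_z=0.0, station=None):
    z = frame.axial_coordinate(bone.vertices)
    s = station if station is not None else (z.max() - z.min()) / 2
    stations, points = centerline(bone, frame=frame, stations=np.array([s]))
    return OsteotomyPlane.from_parameters(frame, points[0], stations[0], tilt_a, tilt_z)


class TestCenterline:
    def test_straight_cylinder_centerline_on_axis(self, cylinder):
        frame = BoneFrame.from_mesh(cylinder)
        _, pts = centerline(cylinder, n_samples=20, frame=frame)
        np.testing.assert_allclose(pts[:, :2], 0.0, atol=1e-3)

    def test_ordered_proximal_to_distal(self, bone, frame):
        s, pts = centerline(bone, n_samples=30, frame=frame)
        assert np.all(np.diff(s) > 0)
        assert np.all(np.diff(pts[:, 2]) > 0)

    def test_sphere_rejected(self, sphere10):
        with pytest.raises(ValueError):
            centerline(sphere10, n_samples=10)

    def test_bent_bone_kinks_at_station(self):
        # the deformed centerline's distal segment rotates by the wedge angle
        # relative to the healthy centerline; the shared bow cancels out
        spec = SyntheticCaseSpec(seed=3, wedge_angle=np.deg2rad(20), wedge_station=60.0)
        healthy, _ = make_healthy_bone(spec)
        deformed, _ = apply_wedge(healthy, spec)
        sh, ph = centerline(healthy, n_samples=40, frame=BoneFrame(np.zeros(3), np.eye(3)))
        sd, pd = centerline(deformed, n_samples=40, frame=BoneFrame(np.zeros(3), np.eye(3)))

        def seg_dir(pts, a, b):
            d = pts[b] - pts[a]
            return d / np.linalg.norm(d)

        prox_rot = np.degrees(np.arccos(np.clip(seg_dir(pd, 2, 12) @ seg_dir(ph, 2, 12), -1, 1)))
        dist_rot = np.degrees(np.arccos(np.clip(seg_dir(pd, -13, -3) @ seg_dir(ph, -13, -3), -1, 1)))
        assert prox_rot < 2.0
        assert dist_rot == pytest.approx(20.0, abs=2.0)


class TestCutWithPlane:
    def test_transverse_mid_cut_halves_volume(self, cylinder):
        frame = BoneFrame.from_mesh(cylinder)
        plane = mid_plane(cylinder, frame)
        prox, dist = cut_with_plane(cylinder, plane)
        v0 = mesh_volume(cylinder)
        vp, vd = mesh_volume(prox.mesh), mesh_volume(dist.mesh)
        assert vp + vd == pytest.approx(v0, rel=1e-3)
        assert vp == pytest.approx(v0 / 2, rel=5e-3)

    def test_thirty_percent_station(self, cylinder):
        frame = BoneFrame.from_mesh(cylinder)
        plane = mid_plane(cylinder, frame, station=30.0)
        prox, dist = cut_with_plane(cylinder, plane)
        v0 = mesh_volume(cylinder)
        assert mesh_volume(prox.mesh) / v0 == pytest.approx(0.30, abs=0.005)

    def test_volume_conserved_on_bone_with_tilts(self, bone, frame, rng):
        v0 = mesh_volume(bone)
        for _ in range(5):
            plane = mid_plane(
                bone,
                frame,
                tilt_a=rng.uniform(-0.6, 0.6),
                tilt_z=rng.uniform(-0.6, 0.6),
                station=rng.uniform(30, 90),
            )
            prox, dist = cut_with_plane(bone, plane)
            assert prox.mesh.is_watertight() and dist.mesh.is_watertight()
            total = mesh_volume(prox.mesh) + mesh_volume(dist.mesh)
            assert total == pytest.approx(v0, rel=1e-3)

    def test_nonintersecting_plane_errors(self, bone, frame):
        plane = OsteotomyPlane.from_parameters(frame, np.array([0.0, 0.0, -50.0]), -50.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            cut_with_plane(bone, plane)


class TestReconstructAndObjective:
    def test_identity_transforms_leave_fragments(self, bone, frame):
        plane = mid_plane(bone, frame)
        prox, dist = cut_with_plane(bone, plane)
        rp, rd = reconstruct(prox, dist, RigidTransform.identity(), RigidTransform.identity())
        np.testing.assert_array_equal(rp.mesh.vertices, prox.mesh.vertices)
        assert objective(rp, rd) == pytest.approx(0.0, abs=1e-9)

    def test_vertices_match_matrix_oracle(self, bone, frame, rng):
        plane = mid_plane(bone, frame)
        prox, dist = cut_with_plane(bone, plane)
        t = random_rigid(rng, max_angle=0.5, max_translation=10.0)
        rp, _ = reconstruct(prox, dist, t, RigidTransform.identity())
        expect = prox.mesh.vertices @ t.rotation.T + t.translation
        np.testing.assert_allclose(rp.mesh.vertices, expect, atol=1e-12)

    def test_normal_offset_gap_is_exact(self, bone, frame):
        plane = mid_plane(bone, frame)
        prox, dist = cut_with_plane(bone, plane)
        shift = RigidTransform.from_rotation_translation(np.eye(3), 2.0 * plane.normal)
        rp, rd = reconstruct(prox, dist, RigidTransform.identity(), shift)
        assert objective(rp, rd) == pytest.approx(2.0, abs=1e-6)

    def test_overlap_term_only_subtracts(self, bone, frame):
        plane = mid_plane(bone, frame)
        prox, dist = cut_with_plane(bone, plane)
        rp, rd = reconstruct(prox, dist, RigidTransform.identity(), RigidTransform.identity())
        base = objective(rp, rd)
        with_overlap = objective(rp, rd, contralateral=bone, overlap_weight=0.5)
        assert with_overlap <= base

    def test_missing_tags_error(self, bone, frame):
        from osteoplan.planner import CutFragment

        plane = mid_plane(bone, frame)
        prox, dist = cut_with_plane(bone, plane)
        broken = CutFragment(prox.mesh, np.empty(0, dtype=np.int64), "proximal")
        with pytest.raises(ValueError, match="tags"):
            objective(broken, dist)


class TestExhaustiveSearch:
    def test_null_deformity_fixed_point(self, bone):
        prox, dist = register_joint_ends(bone, bone)
        res = exhaustive_search(bone, bone, prox.transform, dist.transform)
        assert res.objective < 0.1
        from osteoplan.geometry import decompose_euler

        d = decompose_euler(res.realignment)
        assert np.rad2deg(d.R) < 0.1
        assert d.T < 0.1

    def test_single_node_grid_returns_that_node(self, bone):
        grid = SearchGrid(
            station_step=1000.0, station_span=(0.5, 0.51), tilt_limit=0.01, tilt_step=1.0
        )
        res = exhaustive_search(
            bone, bone, RigidTransform.identity(), RigidTransform.identity(), grid=grid
        )
        assert res.n_grid_nodes == 1
        assert res.plane.tilt_a == 0.0 and res.plane.tilt_z == 0.0

    def test_matches_naive_full_reevaluation(self, bone):
        # independent oracle: every (station, tilt, tilt) node evaluated by a
        # fresh contour + symmetric nearest-neighbour gap, minimum by the
        # same deterministic tie-break
        import trimesh.intersections as ti
        from scipy.spatial import cKDTree

        m_prox = RigidTransform.from_axis_angle([0, 1, 0], 0.02, point=[0, 0, 60])
        m_dist = RigidTransform.from_axis_angle([1, 0, 0], -0.03, point=[0, 0, 60])
        grid = SearchGrid(station_step=8.0, station_span=(0.3, 0.7), tilt_limit=np.deg2rad(30), tilt_step=np.deg2rad(15))
        frame = BoneFrame.from_mesh(bone)
        res = exhaustive_search(bone, bone, m_prox, m_dist, grid=grid, frame=frame)

        z = frame.axial_coordinate(bone.vertices)
        extent = z.max() - z.min()
        stations = grid.stations(extent)
        s_kept, pts = centerline(bone, frame=frame, stations=stations)
        tm = bone.to_trimesh()
        best = None
        mid = extent / 2
        for s, p in zip(s_kept, pts):
            for ta in grid.tilts():
                for tz in grid.tilts():
                    plane = OsteotomyPlane.from_parameters(frame, p, s, ta, tz)
                    seg = ti.mesh_plane(tm, plane.normal, plane.point)
                    if len(seg) == 0:
                        continue
                    c = seg.reshape(-1, 3)
                    a, b = m_prox.apply(c), m_dist.apply(c)
                    gap = np.concatenate(
                        [cKDTree(b).query(a)[0], cKDTree(a).query(b)[0]]
                    ).mean()
                    key = (gap, abs(s - mid), s, ta, tz)
                    if best is None or key < best:
                        best = key
        assert res.objective == best[0]
        assert res.plane.station == best[2]
        assert (res.plane.tilt_a, res.plane.tilt_z) == (best[3], best[4])


class TestSecondaryCut:
    def test_opening_wedge_has_no_secondary(self, bone):
        frame = BoneFrame.from_mesh(bone)
        plane = mid_plane(bone, frame)
        from osteoplan.planner import PlanningResult

        pull = RigidTransform.from_rotation_translation(np.eye(3), 3.0 * plane.normal)
        prox, dist = cut_with_plane(bone, plane)
        rp, rd = reconstruct(prox, dist, RigidTransform.identity(), pull)
        res = PlanningResult(
            plane=plane,
            proximal_fragment=rp,
            distal_fragment=rd,
            m_prox=RigidTransform.identity(),
            m_dist=pull,
            realignment=pull,
            objective=3.0,
            wedge_type="opening",
        )
        out = secondary_cut(res, bone)
        assert out.secondary_plane is None

    @pytest.mark.parametrize(
        "station,angle_deg,expect_red", [(60.0, 12.0, True), (100.0, 30.0, False)]
    )
    def test_closing_wedge_flag_matches_polygon_oracle(self, bone, station, angle_deg, expect_red):
        # hinge the distal fragment: planes meeting inside the bone section
        # cross the primary cut (red); with the apex far outside the section
        # (large angle, cut far distal to the hinge) they do not (green)
        frame = BoneFrame.from_mesh(bone)
        plane = mid_plane(bone, frame, station=station)
        hinge = RigidTransform.from_axis_angle([0, 1, 0], np.deg2rad(angle_deg), point=[0, 0, 60.0])
        prox, dist = cut_with_plane(bone, plane)
        rp, rd = reconstruct(prox, dist, RigidTransform.identity(), hinge)
        from osteoplan.planner import PlanningResult, _wedge_type

        wedge = _wedge_type(plane, rp, rd, RigidTransform.identity())
        res = PlanningResult(
            plane=plane,
            proximal_fragment=rp,
            distal_fragment=rd,
            m_prox=RigidTransform.identity(),
            m_dist=hinge,
            realignment=hinge,
            objective=0.0,
            wedge_type=wedge,
        )
        out = secondary_cut(res, bone)
        assert wedge == "closing"
        assert out.secondary_plane is not None
        # oracle: do the two cut polygons straddle each other's planes?
        c1 = cut_contour(bone, plane)
        s2 = (c1 - out.secondary_plane.point) @ out.secondary_plane.normal
        oracle = bool(s2.min() < -1e-6 and s2.max() > 1e-6)
        assert out.secondary_intersects_primary == oracle
        assert out.secondary_intersects_primary == expect_red


class TestComparePlanes:
    def _result(self, plane, bone):
        from osteoplan.planner import PlanningResult

        prox, dist = cut_with_plane(bone, plane)
        return PlanningResult(
            plane=plane,
            proximal_fragment=prox,
            distal_fragment=dist,
            m_prox=RigidTransform.identity(),
            m_dist=RigidTransform.identity(),
            realignment=RigidTransform.identity(),
            objective=0.0,
            wedge_type="opening",
            bone="radius",
        )

    def test_same_plan_all_zero(self, bone, frame):
        a = self._result(mid_plane(bone, frame), bone)
        cmp = compare_planes(a, a, frame)
        assert (cmp.delta_z, cmp.psi_a, cmp.psi_z) == (0.0, 0.0, 0.0)

    def test_axial_shift_signed_distal_positive(self, bone, frame):
        a = self._result(mid_plane(bone, frame, station=55.0), bone)
        b = self._result(mid_plane(bone, frame, station=60.0), bone)
        cmp = compare_planes(a, b, frame)
        assert cmp.delta_z == pytest.approx(5.0, abs=0.2)
        assert compare_planes(b, a, frame).delta_z == pytest.approx(-5.0, abs=0.2)

    def test_tilt_about_first_axis_shows_in_psi_a(self, bone, frame):
        a = self._result(mid_plane(bone, frame), bone)
        b = self._result(mid_plane(bone, frame, tilt_a=np.deg2rad(10.0)), bone)
        cmp = compare_planes(a, b, frame)
        assert np.rad2deg(cmp.psi_a) == pytest.approx(10.0, abs=1e-6)
        assert cmp.psi_z == pytest.approx(0.0, abs=1e-9)

    def test_mismatched_bones_error(self, bone, frame):
        a = self._result(mid_plane(bone, frame), bone)
        b = self._result(mid_plane(bone, frame), bone)
        b.bone = "ulna"
        with pytest.raises(ValueError, match="bone"):
            compare_planes(a, b, frame)
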