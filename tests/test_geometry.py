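"""Geometric substrate: volumes, meshes, rigid transforms, Euler decomposition."""

import numpy as np
import pytest

from osteoplan.geometry import (
    EulerDecomposition,
    GimbalLockError,
    LabelVolume,
    RigidTransform,
    SurfaceMesh,
    SurfaceQuery,
    compose,
    decompose_euler,
    invert,
    mesh_from_labels,
    mesh_volume,
    mirror_sagittal,
    principal_axis,
    realignment_distance,
    recompose_euler,
    relative,
    resample_isotropic,
)

from conftest import random_rigid


class TestLabelVolume:
    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            LabelVolume(np.zeros((3, 3, 3)), 0.5)  # float dtype
        with pytest.raises(ValueError):
            LabelVolume(np.zeros((3, 3, 3), dtype=np.int16), -1.0)
        with pytest.raises(ValueError):
            LabelVolume(np.ones((3, 3, 3), dtype=np.int16) * 7, 0.5, label_map={"radius": 1})

    def test_mask_lookup(self, cube_mask):
        assert cube_mask.mask("radius").sum() == 40**3
        with pytest.raises(KeyError):
            cube_mask.mask("femur")


class TestResample:
    def test_empty_volume_stays_empty(self):
        vol = LabelVolume(np.zeros((8, 8, 8), dtype=np.int16), 1.0)
        out = resample_isotropic(vol, 0.5)
        assert out.spacing == 0.5
        assert not out.array.any()

    def test_identity_spacing_is_noop(self, cube_mask):
        out = resample_isotropic(cube_mask, 0.5)
        np.testing.assert_array_equal(out.array, cube_mask.array)

    def test_cube_volume_preserved(self):
        # 10 mm cube at 1.0 mm spacing -> 0.5 mm spacing, 1000 mm^3 within 5%
        arr = np.zeros((14, 14, 14), dtype=np.int16)
        arr[2:12, 2:12, 2:12] = 1
        vol = LabelVolume(arr, 1.0, label_map={"radius": 1})
        out = resample_isotropic(vol, 0.5)
        volume = out.array.astype(bool).sum() * out.spacing**3
        assert volume == pytest.approx(1000.0, rel=0.05)

    def test_invalid_spacing(self, cube_mask):
        with pytest.raises(ValueError):
            resample_isotropic(cube_mask, 0.0)


class TestMeshFromLabels:
    def test_single_voxel_is_inscribed_octahedron(self):
        arr = np.zeros((5, 5, 5), dtype=np.int16)
        arr[2, 2, 2] = 1
        vol = LabelVolume(arr, 0.5, label_map={"radius": 1})
        mesh = mesh_from_labels(vol, "radius")
        assert mesh.is_watertight()
        # the 0.5 iso-surface of a lone voxel is the inscribed octahedron
        # with half-diagonal s/2: volume 4/3·(s/2)³
        assert mesh_volume(mesh) == pytest.approx(4 / 3 * 0.25**3, rel=1e-6)

    def test_cube_volume_analytic(self, cube_mask):
        mesh = mesh_from_labels(cube_mask, "radius")
        assert mesh.is_watertight()
        assert mesh_volume(mesh) == pytest.approx((40 * 0.5) ** 3, rel=0.05)

    def test_empty_label_errors(self):
        vol = LabelVolume(np.zeros((4, 4, 4), dtype=np.int16), 0.5, label_map={"radius": 1})
        with pytest.raises(ValueError, match="empty"):
            mesh_from_labels(vol, "radius")

    def test_multi_component_keeps_largest(self):
        arr = np.zeros((12, 12, 12), dtype=np.int16)
        arr[1:7, 1:7, 1:7] = 1
        arr[9, 9, 9] = 1
        vol = LabelVolume(arr, 0.5, label_map={"radius": 1})
        with pytest.warns(UserWarning, match="component"):
            mesh = mesh_from_labels(vol, "radius")
        assert mesh_volume(mesh) == pytest.approx((6 * 0.5) ** 3, rel=0.1)

    def test_physical_coordinates(self):
        arr = np.zeros((6, 6, 6), dtype=np.int16)
        arr[2:4, 2:4, 2:4] = 1
        vol = LabelVolume(arr, 2.0, origin=np.array([10.0, -5.0, 3.0]), label_map={"radius": 1})
        mesh = mesh_from_labels(vol, "radius")
        centre = mesh.vertices.mean(axis=0)
        np.testing.assert_allclose(centre, [10.0 + 5.0, -5.0 + 5.0, 3.0 + 5.0], atol=0.5)


class TestMirror:
    def test_involution(self, sphere10):
        twice = mirror_sagittal(mirror_sagittal(sphere10))
        np.testing.assert_allclose(twice.vertices, sphere10.vertices, atol=1e-12)
        np.testing.assert_array_equal(twice.faces, sphere10.faces)

    def test_volume_preserved(self, cylinder):
        assert abs(mesh_volume(mirror_sagittal(cylinder)) - mesh_volume(cylinder)) < 1e-9

    def test_reflects_x(self, unit_cube):
        shifted = SurfaceMesh(unit_cube.vertices + [3.0, 0, 0], unit_cube.faces)
        mirrored = mirror_sagittal(shifted)
        assert mirrored.vertices[:, 0].mean() == pytest.approx(-3.0)


class TestTransformAlgebra:
    def test_relative_self_is_identity(self, rng):
        m = random_rigid(rng)
        np.testing.assert_allclose(relative(m, m).matrix, np.eye(4), atol=1e-12)

    def test_compose_invert_identity(self, rng):
        m = random_rigid(rng)
        np.testing.assert_allclose(compose(m, invert(m)).matrix, np.eye(4), atol=1e-12)

    def test_relative_matches_matrix_product(self, rng):
        for _ in range(50):
            a, b = random_rigid(rng), random_rigid(rng)
            expect = np.linalg.inv(a.matrix) @ b.matrix
            np.testing.assert_allclose(relative(a, b).matrix, expect, atol=1e-12)

    def test_composition_associative(self, rng):
        a, b, c = (random_rigid(rng) for _ in range(3))
        np.testing.assert_allclose(
            compose(compose(a, b), c).matrix, compose(a, compose(b, c)).matrix, atol=1e-12
        )

    def test_rejects_reflection_and_nonrigid(self):
        m = np.diag([-1.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            RigidTransform(m)
        m2 = np.eye(4)
        m2[0, 0] = 2.0
        with pytest.raises(ValueError):
            RigidTransform(m2)


class TestEulerDecomposition:
    def test_pure_translation(self):
        m = RigidTransform.from_rotation_translation(np.eye(3), [3.0, 4.0, 0.0])
        d = decompose_euler(m)
        assert (d.dx, d.dy, d.dz) == (3.0, 4.0, 0.0)
        assert d.R == 0.0
        assert d.T == pytest.approx(5.0)

    def test_single_axis_rotation(self):
        m = RigidTransform.from_axis_angle([1.0, 0, 0], np.pi / 6)
        d = decompose_euler(m)
        assert d.phi_x == pytest.approx(np.pi / 6)
        assert d.phi_y == pytest.approx(0.0, abs=1e-12)
        assert d.phi_z == pytest.approx(0.0, abs=1e-12)
        assert d.R == pytest.approx(np.pi / 6)
        assert d.T == 0.0

    def test_known_angle_triplet(self):
        rx = RigidTransform.from_axis_angle([1, 0, 0], 0.3)
        ry = RigidTransform.from_axis_angle([0, 1, 0], 0.2)
        rz = RigidTransform.from_axis_angle([0, 0, 1], 0.1)
        m = compose(rz, compose(ry, rx))  # R = Rz·Ry·Rx
        d = decompose_euler(m)
        np.testing.assert_allclose([d.phi_x, d.phi_y, d.phi_z], [0.3, 0.2, 0.1], atol=1e-9)

    def test_round_trip_many(self, rng):
        # large sweep: decompose/recompose closes within 1e-9 on all entries
        n = 10_000
        for _ in range(n):
            m = random_rigid(rng)
            try:
                d = decompose_euler(m)
            except GimbalLockError:
                continue
            np.testing.assert_allclose(recompose_euler(d).matrix, m.matrix, atol=1e-9)

    def test_angle_domains(self, rng):
        for _ in range(500):
            m = random_rigid(rng)
            try:
                d = decompose_euler(m)
            except GimbalLockError:
                continue
            assert -np.pi <= d.phi_x <= np.pi
            assert -np.pi / 2 <= d.phi_y <= np.pi / 2
            assert -np.pi <= d.phi_z <= np.pi

    def test_gimbal_lock_is_an_error(self):
        m = RigidTransform.from_axis_angle([0, 1, 0], np.pi / 2)
        with pytest.raises(GimbalLockError):
            decompose_euler(m)


class TestRealignmentDistance:
    def test_identity(self):
        d = EulerDecomposition(1, 2, 3, 0.1, 0.2, 0.3)
        assert realignment_distance(d, d) == (0.0, 0.0)

    def test_three_four_five(self):
        a = EulerDecomposition(3, 4, 0, 0.1, 0.2, 0.3)
        b = EulerDecomposition(0, 0, 0, 0.1, 0.2, 0.3)
        dt, pr = realignment_distance(a, b)
        assert dt == pytest.approx(5.0)
        assert pr == 0.0

    def test_matches_direct_formula_and_symmetry(self, rng):
        for _ in range(100):
            va, vb = rng.standard_normal(6), rng.standard_normal(6)
            a = EulerDecomposition(*va)
            b = EulerDecomposition(*vb)
            dt, pr = realignment_distance(a, b)
            assert dt == pytest.approx(np.linalg.norm(va[:3] - vb[:3]), abs=1e-12)
            assert pr == pytest.approx(np.linalg.norm(va[3:] - vb[3:]), abs=1e-12)
            assert realignment_distance(b, a) == (dt, pr)


class TestPrincipalAxis:
    def test_cylinder_axis(self, cylinder):
        axis, anchor = principal_axis(cylinder)
        np.testing.assert_allclose(np.abs(axis), [0, 0, 1], atol=1e-6)
        assert axis[2] > 0  # default hint points distal = +z
        assert anchor[2] == pytest.approx(0.0, abs=1e-6)

    def test_rotated_cylinder(self, cylinder, rng):
        r = random_rigid(rng, max_translation=0.0)
        rotated = cylinder.transformed(r)
        axis, _ = principal_axis(rotated, proximal_hint=r.apply_vector([[0, 0, 1.0]])[0])
        np.testing.assert_allclose(axis, r.apply_vector([[0, 0, 1.0]])[0], atol=1e-6)

    def test_sphere_is_degenerate(self, sphere10):
        with pytest.raises(ValueError):
            principal_axis(sphere10)


class TestMeshVolume:
    def test_unit_cube(self, unit_cube):
        assert mesh_volume(unit_cube) == pytest.approx(1.0, abs=1e-12)

    def test_sphere(self, sphere10):
        assert mesh_volume(sphere10) == pytest.approx(4 / 3 * np.pi * 1000.0, rel=0.01)

    def test_open_mesh_errors(self, unit_cube):
        broken = SurfaceMesh(unit_cube.vertices, unit_cube.faces[:-1])
        with pytest.raises(ValueError, match="watertight"):
            mesh_volume(broken)


class TestSurfaceQuery:
    def test_candidate_query_matches_brute_force(self, sphere10, rng):
        q = SurfaceQuery(sphere10)
        pts = rng.uniform(-15, 15, (200, 3))
        fast = q.distances(pts)
        exact = q.distances(pts, exact=True)
        np.testing.assert_allclose(fast, exact, atol=1e-9)

    def test_on_surface_distance_zero(self, unit_cube):
        q = SurfaceQuery(unit_cube)
        d = q.distances(unit_cube.vertices)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)
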