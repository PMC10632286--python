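import numpy as np
import pytest
import trimesh

from osteoplan.geometry import LabelVolume, RigidTransform, SurfaceMesh


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    tm = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name="cube")


@pytest.fixture
def sphere10() -> SurfaceMesh:
    tm = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), name="sphere")


@pytest.fixture
def cylinder() -> SurfaceMesh:
    tm = trimesh.creation.cylinder(radius=5.0, height=100.0, sections=48)
    v = np.asarray(tm.vertices)
    v = v + np.array([0.0, 0.0, 50.0])  # proximal end at z=0
    return SurfaceMesh(v, np.asarray(tm.faces), name="cylinder")


def random_rigid(rng, max_angle=np.pi, max_translation=50.0) -> RigidTransform:
    """Random proper rigid transform (uniform axis, bounded angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    t = rng.uniform(-max_translation, max_translation, 3)
    m = RigidTransform.from_axis_angle(axis, angle)
    return RigidTransform.from_rotation_translation(m.rotation, t)


@pytest.fixture
def cube_mask():
    """20 mm cube mask centred in a 0.5 mm-spacing grid."""
    arr = np.zeros((60, 60, 60), dtype=np.int16)
    arr[10:50, 10:50, 10:50] = 1
    return LabelVolume(arr, 0.5, np.zeros(3), {"radius": 1})
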