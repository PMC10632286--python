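"""Synthetic paired healthy/deformed long-bone phantoms.

Real patient scans behind the planning problem are not publicly available,
so this module generates geometric long-bone phantoms that exercise every
part of the workflow with known ground truth:

* a lofted tube with flared ends (shaft + epiphyses) and a mild, twisting
  azimuthal asymmetry of the cross-section — the asymmetry is what makes
  rigid registration rotationally well-posed;
* a planted wedge deformity of known angle, axis and axial station, applied
  as a smooth rotation blend (±2 mm band) so the warped mesh stays manifold;
* articular-cartilage caps of controllable thickness (driven downward by an
  age proxy, emulating endochondral ossification);
* boundary-noise perturbations calibrated to a commanded mean absolute
  surface distance, standing in for CT-versus-MRI segmentation differences.

Every output is a deterministic function of the spec and its seed.  The
"contralateral healthy" bone is the pre-deformation mesh mirrored
sagittally, so the mirrored contralateral is exactly congruent with the
ideal correction and the ideal planning objective is ~0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import (
    LabelVolume,
    RigidTransform,
    SurfaceMesh,
    mirror_sagittal,
)
from .metrics import masd as _masd
from .planner import BoneFrame, OsteotomyPlane

__all__ = [
    "SyntheticCaseSpec",
    "GroundTruth",
    "SyntheticCase",
    "make_healthy_bone",
    "apply_wedge",
    "add_cartilage_caps",
    "perturb_segmentation",
    "generate_cohort",
]

VOXEL_SPACING = 0.5  # mm, the isotropic working resolution
BLEND_BAND = 2.0  # mm default half-width of the smooth wedge blend
_MAX_BLEND_SLOPE = 0.85  # injectivity margin of the blend warp


def _blend_band(spec: "SyntheticCaseSpec") -> float:
    """Blend half-width, widened for large angles so the warp stays injective.

    The warp folds (surface self-intersects) when the blend slope times the
    lever arm from the hinge reaches 1; the band grows just enough to keep
    that product at ``_MAX_BLEND_SLOPE``.
    """
    lever = np.hypot(spec.shaft_radius * (1.0 + 2.0 * spec.asymmetry), BLEND_BAND)
    needed = 1.5 * spec.wedge_angle * lever / (2.0 * _MAX_BLEND_SLOPE)
    return float(max(BLEND_BAND, needed))
LABELS = {"radius": 1, "cartilage": 2}


@dataclass(frozen=True)
class SyntheticCaseSpec:
    """Generative parameters of one synthetic case."""

    seed: int = 0
    length: float = 120.0  # mm
    shaft_radius: float = 4.0  # mm
    epiphysis_radius: float = 7.0  # mm
    wedge_angle: float = np.deg2rad(20.0)  # rad
    wedge_axis: tuple = (0.0, 1.0, 0.0)  # unit vector ⊥ long axis (z)
    wedge_station: float = 60.0  # mm from the proximal end
    cartilage_thickness: float = 1.5  # mm per end
    age_proxy: float = 12.0  # years
    noise_masd_target: float = 0.42  # mm
    asymmetry: float = 0.15  # relative cross-section modulation (non-circular shaft)
    bow: float = 4.0  # mm lateral bow of the shaft (like the radial bow)
    ring_step: float = 1.5  # mm between mesh rings
    n_circumference: int = 40

    def __post_init__(self):
        if not (0.0 < self.wedge_station < self.length):
            raise ValueError("wedge_station must lie strictly inside the bone")
        if not (0.0 <= self.wedge_angle <= np.deg2rad(45.0)):
            raise ValueError("wedge_angle must lie in [0, 45 degrees]")
        if min(self.shaft_radius, self.epiphysis_radius) <= 0 or self.length <= 0:
            raise ValueError("all dimensions must be positive")
        ax = np.asarray(self.wedge_axis, float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-6 or abs(ax[2]) > 1e-9:
            raise ValueError("wedge_axis must be a unit vector perpendicular to z")


@dataclass(frozen=True)
class GroundTruth:
    """Exact generative answers a planner should recover."""

    true_realignment: RigidTransform
    true_plane: OsteotomyPlane
    true_rcv: float
    wedge_angle: float
    wedge_axis: np.ndarray
    wedge_station: float
    anchor: np.ndarray


@dataclass
class SyntheticCase:
    """One complete runnable case: meshes, volumes, variants, ground truth."""

    spec: SyntheticCaseSpec
    healthy_mesh: SurfaceMesh
    contralateral_mesh: SurfaceMesh  # mirrored healthy bone (the "other arm")
    deformed_mesh: SurfaceMesh
    volumes: dict = field(default_factory=dict)  # method tag -> deformed-side LabelVolume
    healthy_volumes: dict = field(default_factory=dict)  # "bone" | "bone_cartilage" -> LabelVolume
    truth: GroundTruth | None = None
    age: float = 12.0


# ---------------------------------------------------------------------------
# analytic bone shape
# ---------------------------------------------------------------------------


def _radius_profile(spec: SyntheticCaseSpec, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Axial radius profile and flare weight.

    Shaft with smoothstep flares into the epiphyses; the two ends are
    deliberately different (narrow proximal head, wide distal end, like a
    radius) so the bone has no end-for-end symmetry and alignment is
    globally well-posed.  Returns ``(radius, flare)`` with flare in [0, 1]
    peaking at the ends — the epiphyseal ellipticity is scaled by it.
    """

    def smoothstep(t):
        t = np.clip(t, 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)

    prox = smoothstep(1.0 - z / (0.10 * spec.length))
    dist = smoothstep(1.0 - (spec.length - z) / (0.18 * spec.length))
    r_prox = spec.shaft_radius + (0.7 * spec.epiphysis_radius - spec.shaft_radius) * prox
    r_dist = spec.shaft_radius + (spec.epiphysis_radius - spec.shaft_radius) * dist
    return np.maximum(r_prox, r_dist), np.maximum(prox, dist)


def _phases(spec: SyntheticCaseSpec) -> tuple[float, ...]:
    rng = np.random.default_rng(spec.seed)
    phi1, phi2, phi3, phi4, phi5, phi_bow = rng.uniform(0.0, 2 * np.pi, size=6)
    twist = rng.uniform(0.003, 0.008)  # rad per mm, slow azimuthal twist
    return float(phi1), float(phi2), float(phi3), float(phi4), float(phi5), float(phi_bow), float(twist)


def _bow_center(spec: SyntheticCaseSpec, z: np.ndarray) -> np.ndarray:
    """Transverse offset of the cross-section centre: the shaft's bow.

    A single arch (zero at both ends) in a seeded direction — the dominant
    large-scale asymmetry of a real radius, and the feature that makes the
    bone's spin about its long axis unambiguous at segmentation-noise scale.
    """
    phi_bow = _phases(spec)[5]
    arch = spec.bow * np.sin(np.pi * np.clip(np.asarray(z, float), 0.0, spec.length) / spec.length)
    return np.stack([arch * np.cos(phi_bow), arch * np.sin(phi_bow)], axis=-1)


_RIPPLE_PERIOD = 23.0  # mm; longitudinal thickness ripple
_RIPPLE_AMP = 0.05
_EPIPHYSIS_ELLIPTICITY = 0.22  # relative cos 2θ amplitude at the joint ends
_STYLOID_AMP = 0.18  # relative cos θ amplitude at the joint ends (breaks 180°)


def _boundary_radius(spec: SyntheticCaseSpec, theta: np.ndarray, z: np.ndarray) -> np.ndarray:
    """r(θ, z): axial profile with twisting cos θ / cos 2θ modulation, a
    longitudinal ripple, and elliptical epiphyses.

    The azimuthal terms make the cross-section non-circular (spin is
    observable), the ripple makes the radius vary along the shaft (axial
    slide is observable), and the coarse ellipticity of the joint ends —
    like a real distal radius — keeps the spin observable even after
    voxelization and boundary noise.
    """
    phi1, phi2, phi3, phi4, phi5, _, twist = _phases(spec)
    base, flare = _radius_profile(spec, z)
    mod = 1.0 + spec.asymmetry * np.cos(theta - phi1 - twist * z) \
        + 0.5 * spec.asymmetry * np.cos(2.0 * (theta - phi2 + 0.5 * twist * z)) \
        + _RIPPLE_AMP * np.cos(2.0 * np.pi * z / _RIPPLE_PERIOD + phi3) \
        + _EPIPHYSIS_ELLIPTICITY * flare * np.cos(2.0 * (theta - phi4)) \
        + _STYLOID_AMP * flare * np.cos(theta - phi5)
    return base * mod


def _inside_healthy(spec: SyntheticCaseSpec, points: np.ndarray) -> np.ndarray:
    p = np.asarray(points, float)
    z = p[..., 2]
    zc = np.clip(z, 0.0, spec.length)
    centre = _bow_center(spec, zc)
    dx = p[..., 0] - centre[..., 0]
    dy = p[..., 1] - centre[..., 1]
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)
    return (z >= 0.0) & (z <= spec.length) & (r <= _boundary_radius(spec, theta, zc))


def make_healthy_bone(spec: SyntheticCaseSpec) -> tuple[SurfaceMesh, LabelVolume]:
    """Watertight healthy-bone mesh and its 0.5 mm label volume.

    The mesh is a loft of analytic cross-sections capped with centre fans at
    both ends; the volume is the same analytic solid sampled at voxel
    centres, so the two representations agree to voxel precision.
    """
    n_rings = max(2, int(round(spec.length / spec.ring_step)) + 1)
    zs = np.linspace(0.0, spec.length, n_rings)
    thetas = np.arange(spec.n_circumference) / spec.n_circumference * 2 * np.pi
    verts = []
    for z in zs:
        r = _boundary_radius(spec, thetas, np.full_like(thetas, z))
        cx, cy = _bow_center(spec, np.array([z]))[0]
        verts.append(
            np.column_stack(
                [cx + r * np.cos(thetas), cy + r * np.sin(thetas), np.full_like(thetas, z)]
            )
        )
    verts = np.vstack(verts)
    nc = spec.n_circumference
    faces = []
    for i in range(n_rings - 1):
        a = i * nc + np.arange(nc)
        b = i * nc + (np.arange(nc) + 1) % nc
        c = (i + 1) * nc + np.arange(nc)
        d = (i + 1) * nc + (np.arange(nc) + 1) % nc
        faces.append(np.column_stack([a, b, d]))
        faces.append(np.column_stack([a, d, c]))
    # end caps: centre-vertex fans (bottom winds downward, top upward)
    bottom_c = len(verts)
    top_c = len(verts) + 1
    verts = np.vstack([verts, [[0.0, 0.0, 0.0]], [[0.0, 0.0, spec.length]]])  # bow is zero at the ends
    a = np.arange(nc)
    b = (np.arange(nc) + 1) % nc
    faces.append(np.column_stack([b, a, np.full(nc, bottom_c)]))
    top = (n_rings - 1) * nc
    faces.append(np.column_stack([top + a, top + b, np.full(nc, top_c)]))
    mesh = SurfaceMesh(verts, np.vstack(faces), name="radius")
    tm = mesh.to_trimesh()
    if tm.volume < 0:
        mesh = SurfaceMesh(mesh.vertices, mesh.faces[:, ::-1], name="radius")

    vol = _voxelize(spec, deformed=False)
    return mesh, vol


# ---------------------------------------------------------------------------
# wedge deformity
# ---------------------------------------------------------------------------


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def _blend_weight(z: np.ndarray, station: float, band: float = BLEND_BAND) -> np.ndarray:
    return _smoothstep((np.asarray(z, float) - (station - band)) / (2.0 * band))


def _wedge_anchor(spec: SyntheticCaseSpec) -> np.ndarray:
    """Area centroid of the cross-section at the wedge station (analytic)."""
    theta = np.linspace(0.0, 2 * np.pi, 721)[:-1]
    r = _boundary_radius(spec, theta, np.full_like(theta, spec.wedge_station))
    area = 0.5 * np.trapezoid(np.append(r, r[0]) ** 2, dx=2 * np.pi / len(theta))
    cx = np.trapezoid(np.append(r, r[0]) ** 3 * np.cos(np.append(theta, theta[0])), dx=2 * np.pi / len(theta)) / 3.0
    cy = np.trapezoid(np.append(r, r[0]) ** 3 * np.sin(np.append(theta, theta[0])), dx=2 * np.pi / len(theta)) / 3.0
    centre = _bow_center(spec, np.array([spec.wedge_station]))[0]
    return np.array([centre[0] + cx / area, centre[1] + cy / area, spec.wedge_station])


def _rodrigues(axis: np.ndarray, angles: np.ndarray, vectors: np.ndarray) -> np.ndarray:
    """Rotate each vector by its own angle about a common unit axis."""
    angles = np.asarray(angles, float)[..., None]
    a = np.asarray(axis, float)
    cos, sin = np.cos(angles), np.sin(angles)
    cross = np.cross(np.broadcast_to(a, vectors.shape), vectors)
    dot = (vectors @ a)[..., None]
    return vectors * cos + cross * sin + a * dot * (1.0 - cos)


def _warp(spec: SyntheticCaseSpec, points: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Forward wedge warp: rotate by angle·w(z) about the wedge axis at the anchor."""
    w = _blend_weight(points[:, 2], spec.wedge_station, _blend_band(spec))
    return anchor + _rodrigues(np.asarray(spec.wedge_axis), spec.wedge_angle * w, points - anchor)


def _unwarp_z(spec: SyntheticCaseSpec, points: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Original z-coordinate of each warped point, by bisection.

    The forward warp moves a point by a rotation whose angle depends only on
    the original z; recovering z is a 1-D root find, monotone for the wedge
    angles and shaft radii the generator allows.
    """
    p = points - anchor
    axis = np.asarray(spec.wedge_axis, float)
    band = _blend_band(spec)
    full_back = _rodrigues(axis, np.full(len(p), -spec.wedge_angle), p)[:, 2] + anchor[2]
    lo = np.minimum(points[:, 2], full_back) - band - 1.0
    hi = np.maximum(points[:, 2], full_back) + band + 1.0

    def f(z0):
        alpha = spec.wedge_angle * _blend_weight(z0, spec.wedge_station, band)
        back = _rodrigues(axis, -alpha, p)
        return back[:, 2] + anchor[2] - z0

    for _ in range(30):
        mid = 0.5 * (lo + hi)
        pos = f(mid) > 0
        lo = np.where(pos, mid, lo)
        hi = np.where(pos, hi, mid)
    return 0.5 * (lo + hi)


def _inside_deformed(spec: SyntheticCaseSpec, points: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Inside test of the warped solid via the inverse warp.

    Points whose preimage clearly lies proximal (identity) or distal (full
    rotation) of the blend band use the closed-form inverse; only the thin
    slab around the blend needs the bisection.
    """
    points = np.asarray(points, float)
    band = _blend_band(spec)
    s = spec.wedge_station
    axis = np.asarray(spec.wedge_axis, float)
    q = points.copy()
    is_prox = points[:, 2] <= s - band
    full_back = anchor + _rodrigues(axis, np.full(len(points), -spec.wedge_angle), points - anchor)
    is_dist = (~is_prox) & (full_back[:, 2] >= s + band)
    rest = ~(is_prox | is_dist)
    q[is_dist] = full_back[is_dist]
    if rest.any():
        z0 = _unwarp_z(spec, points[rest], anchor)
        alpha = spec.wedge_angle * _blend_weight(z0, s, band)
        q[rest] = anchor + _rodrigues(axis, -alpha, points[rest] - anchor)
    return _inside_healthy(spec, q)


def _voxelize(spec: SyntheticCaseSpec, deformed: bool) -> LabelVolume:
    margin = 2.0
    rmax = spec.epiphysis_radius * (1.0 + 2.0 * spec.asymmetry)
    lo = np.array([-rmax - margin, -rmax - margin, -margin])
    hi = np.array([rmax + margin, rmax + margin, spec.length + margin])
    if deformed and spec.wedge_angle > 0:
        # the rotated distal half sweeps sideways; widen the box
        reach = (spec.length - spec.wedge_station) * np.sin(spec.wedge_angle) + rmax
        lo[:2] = np.minimum(lo[:2], -reach - margin)
        hi[:2] = np.maximum(hi[:2], reach + margin)
    shape = np.ceil((hi - lo) / VOXEL_SPACING).astype(int)
    grids = [lo[i] + (np.arange(shape[i]) + 0.5) * VOXEL_SPACING for i in range(3)]
    pts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, 3)
    if deformed:
        anchor = _wedge_anchor(spec)
        inside = _inside_deformed(spec, pts, anchor)
    else:
        inside = _inside_healthy(spec, pts)
    arr = inside.reshape(tuple(shape)).astype(np.int16) * LABELS["radius"]
    origin = lo + 0.5 * VOXEL_SPACING
    return LabelVolume(arr, VOXEL_SPACING, origin, dict(LABELS))


def apply_wedge(healthy: SurfaceMesh, spec: SyntheticCaseSpec) -> tuple[SurfaceMesh, GroundTruth]:
    """Plant the wedge deformity into the healthy mesh.

    The distal portion is rotated by the wedge angle about the wedge axis
    anchored at the cross-section centroid at the wedge station, with a
    smooth ±2 mm blend.  The ground truth carries the exact inverse
    correction and the bisecting true plane.
    """
    anchor = _wedge_anchor(spec)
    axis = np.asarray(spec.wedge_axis, float)
    # a fold in the blend band means the warped surface self-intersects;
    # the band auto-widens, but the station must leave room for it
    band = _blend_band(spec)
    if not (band < spec.wedge_station < spec.length - band):
        raise ValueError("wedge station too close to a bone end for the blend band")
    deformed = SurfaceMesh(_warp(spec, healthy.vertices, anchor), healthy.faces.copy(), name=healthy.name)
    correction = RigidTransform.from_axis_angle(axis, -spec.wedge_angle, point=anchor)
    frame = BoneFrame(origin=np.zeros(3), axes=np.eye(3))  # generator bones: proximal at z=0
    half_normal = _rodrigues(axis, np.array([spec.wedge_angle / 2.0]), np.array([[0.0, 0.0, 1.0]]))[0]
    true_plane = OsteotomyPlane(
        point=anchor,
        normal=half_normal / np.linalg.norm(half_normal),
        station=spec.wedge_station,
        tilt_a=np.nan,
        tilt_z=np.nan,
        frame=frame,
    )
    truth = GroundTruth(
        true_realignment=correction,
        true_plane=true_plane,
        true_rcv=0.0,
        wedge_angle=spec.wedge_angle,
        wedge_axis=axis,
        wedge_station=spec.wedge_station,
        anchor=anchor,
    )
    return deformed, truth


# ---------------------------------------------------------------------------
# cartilage and segmentation noise
# ---------------------------------------------------------------------------


def add_cartilage_caps(bone_vol: LabelVolume, thickness: float, cap_depth: float | None = None) -> LabelVolume:
    """Grow a cartilage shell of the given thickness over both bone ends.

    The shell is the set of background voxels within `thickness` of the bone
    (Euclidean distance transform), restricted to the terminal `cap_depth`
    of the bone's z-extent.  Relative cartilage volume grows strictly with
    thickness.
    """
    if thickness < 0:
        raise ValueError("thickness must be >= 0")
    out = LabelVolume(bone_vol.array.copy(), bone_vol.spacing, bone_vol.origin.copy(), dict(bone_vol.label_map))
    if thickness == 0:
        out.array[out.array == out.label_map.get("cartilage", -1)] = 0
        return out
    bone = bone_vol.array == bone_vol.label_map["radius"]
    dt = ndimage.distance_transform_edt(~bone) * bone_vol.spacing
    shell = (dt > 0) & (dt <= thickness)
    zidx = np.where(bone.any(axis=(0, 1)))[0]
    z_lo, z_hi = zidx.min(), zidx.max()
    depth_vox = int(round((cap_depth if cap_depth is not None else 10.0) / bone_vol.spacing))
    end_region = np.zeros_like(bone)
    end_region[:, :, : z_lo + depth_vox + 1] = True
    end_region[:, :, z_hi - depth_vox :] = True
    cart = shell & end_region
    out.array[cart] = out.label_map["cartilage"]
    return out


def perturb_segmentation(vol: LabelVolume, masd_target: float, seed: int, label: str = "radius") -> LabelVolume:
    """Displace the label boundary by a smooth random field.

    The mask is represented by its signed Euclidean distance, a smooth
    correlated Gaussian field is added with an amplitude calibrated (by up
    to three measure-and-rescale passes) so the achieved mean absolute
    surface distance is close to `masd_target`, and the result is
    re-thresholded.  Topology is preserved by keeping the largest component;
    an unreachable target raises.
    """
    if masd_target < 0:
        raise ValueError("masd_target must be >= 0")
    out_map = dict(vol.label_map)
    if masd_target == 0:
        return LabelVolume(vol.array.copy(), vol.spacing, vol.origin.copy(), out_map)
    mask = vol.array == vol.label_map[label]
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    sd = (inside - outside) * vol.spacing  # positive inside, mm
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    field = ndimage.gaussian_filter(noise, sigma=3.0)
    field /= field.std()

    base = LabelVolume(mask.astype(np.int16), vol.spacing, vol.origin.copy(), {label: 1})
    amp = masd_target * np.sqrt(np.pi / 2.0)
    achieved = None
    result_mask = None
    for _ in range(4):
        new = (sd + amp * field) > 0
        lab, n = ndimage.label(new)
        if n == 0:
            raise ValueError("masd_target erased the segmentation entirely")
        if n > 1:
            sizes = ndimage.sum_labels(new, lab, index=np.arange(1, n + 1))
            new = lab == (1 + int(np.argmax(sizes)))
        cand = LabelVolume(new.astype(np.int16), vol.spacing, vol.origin.copy(), {label: 1})
        achieved = _masd(base, cand)
        result_mask = new
        if achieved > 0 and abs(achieved - masd_target) / masd_target <= 0.15:
            break
        amp *= masd_target / max(achieved, 1e-9)
    if achieved == 0 or abs(achieved - masd_target) / masd_target > 0.5:
        raise ValueError(f"could not reach MASD target {masd_target}; achieved {achieved}")
    arr = np.where(result_mask, vol.label_map[label], 0).astype(vol.array.dtype)
    keep_other = (vol.array != vol.label_map[label]) & (vol.array != 0) & (arr == 0)
    arr[keep_other] = vol.array[keep_other]
    return LabelVolume(arr, vol.spacing, vol.origin.copy(), out_map)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _cartilage_thickness_for_age(age: float) -> float:
    """Thicker cartilage in younger bones (endochondral ossification proxy)."""
    return 2.5 * np.exp(-0.12 * (age - 7.0))


def make_case(spec: SyntheticCaseSpec, with_variants: bool = True) -> SyntheticCase:
    """Build one complete case from its spec."""
    healthy_mesh, _ = make_healthy_bone(spec)
    contralateral = mirror_sagittal(healthy_mesh)
    deformed_mesh, truth = apply_wedge(healthy_mesh, spec)
    volumes = {}
    healthy_volumes = {}
    if with_variants:
        clean = _voxelize(spec, deformed=True)  # CT-like bone segmentation
        volumes["CTb"] = clean
        volumes["MRb"] = perturb_segmentation(clean, spec.noise_masd_target, seed=spec.seed + 1)
        mrbc = add_cartilage_caps(volumes["MRb"], spec.cartilage_thickness)
        volumes["MRbc"] = mrbc
        # matched healthy-side representations: the contralateral template
        # must carry cartilage when the deformed side does, or the composite
        # surface would be compared against a bare bone
        healthy_clean = _voxelize(spec, deformed=False)
        healthy_volumes["bone"] = healthy_clean
        healthy_volumes["bone_cartilage"] = add_cartilage_caps(healthy_clean, spec.cartilage_thickness)
        cart = int((mrbc.array == LABELS["cartilage"]).sum())
        bone = int((mrbc.array == LABELS["radius"]).sum())
        truth = replace(truth, true_rcv=cart / bone if bone else 0.0)
    return SyntheticCase(
        spec=spec,
        healthy_mesh=healthy_mesh,
        contralateral_mesh=contralateral,
        deformed_mesh=deformed_mesh,
        volumes=volumes,
        healthy_volumes=healthy_volumes,
        truth=truth,
        age=spec.age_proxy,
    )


def generate_cohort(n_cases: int, seed: int = 0, with_variants: bool = True) -> list[SyntheticCase]:
    """Seeded cohort of cases spanning ages 7–18 with varied deformities."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        age = 7.0 + 11.0 * (i + 0.5) / n_cases
        phi = rng.uniform(0.0, 2 * np.pi)
        spec = SyntheticCaseSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            length=float(rng.uniform(100.0, 140.0)),
            shaft_radius=float(rng.uniform(3.5, 4.5)),
            epiphysis_radius=float(rng.uniform(6.0, 8.0)),
            wedge_angle=float(np.deg2rad(rng.uniform(10.0, 30.0))),
            wedge_axis=(float(np.cos(phi)), float(np.sin(phi)), 0.0),
            wedge_station=float(rng.uniform(0.35, 0.65)) * 1.0,  # fraction, fixed below
            cartilage_thickness=float(_cartilage_thickness_for_age(age)),
            age_proxy=float(age),
        )
        spec = replace(spec, wedge_station=spec.wedge_station * spec.length)
        cases.append(make_case(spec, with_variants=with_variants))
    return cases
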