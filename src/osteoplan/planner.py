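"""Virtual osteotomy: plane-parametrized cutting and exhaustive plane search.

Given a deformed bone, the mirrored healthy contralateral template, and the
joint-end registration transforms ``M_prox``/``M_dist``, the planner cuts
the deformed bone with a candidate plane, moves the two fragments with the
saved transforms, and scores the candidate by the residual gap between the
two cut faces (optionally credited by volume overlap with the template).
The best plane over a deterministic grid of centerline stations × transverse
tilts is the planned osteotomy.

The cut plane has six nominal parameters (a centre point constrained to the
bone's axial centerline and three rotations about the bone-local principal
axes), but rotation about the plane normal is a no-op, so the search spans
only the centerline station and the two transverse tilts.

A closing wedge (fragments interpenetrate after reconstruction) needs a
second, mated cut; the planner derives it from the primary plane and the
realignment, and flags whether the two cuts intersect inside the bone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .geometry import (
    RigidTransform,
    SurfaceMesh,
    invert,
    mesh_volume,
    principal_axis,
    relative,
)

__all__ = [
    "BoneFrame",
    "OsteotomyPlane",
    "SearchGrid",
    "CutFragment",
    "PlanningResult",
    "PlaneComparison",
    "bone_frame",
    "centerline",
    "cut_with_plane",
    "reconstruct",
    "objective",
    "cut_contour",
    "exhaustive_search",
    "secondary_cut",
    "compare_planes",
]

#: fragments whose vertices cross the mated cut plane by more than this are
#: considered interpenetrating (closing wedge); well below any real overlap,
#: well above registration round-off.
INTERPENETRATION_TOL = 0.05  # mm


# ---------------------------------------------------------------------------
# frames and planes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BoneFrame:
    """Bone-local frame: origin at the proximal end of the axis, third
    column of `axes` the proximal→distal long axis, first two columns the
    transverse axes the plane tilts rotate about."""

    origin: np.ndarray
    axes: np.ndarray  # 3×3 orthonormal, columns (e_a, e_b, long_axis)

    @classmethod
    def from_mesh(cls, mesh: SurfaceMesh, proximal_hint: np.ndarray | None = None) -> "BoneFrame":
        axis, anchor = principal_axis(mesh, proximal_hint=proximal_hint)
        # deterministic transverse pair: e_a ⟂ axis, seeded from the global
        # axis least aligned with the bone axis
        seed = np.eye(3)[int(np.argmin(np.abs(axis)))]
        e_a = seed - (seed @ axis) * axis
        e_a /= np.linalg.norm(e_a)
        e_b = np.cross(axis, e_a)
        return cls(origin=anchor, axes=np.column_stack([e_a, e_b, axis]))

    @property
    def long_axis(self) -> np.ndarray:
        return self.axes[:, 2]

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, float) - self.origin) @ self.long_axis


@dataclass(frozen=True)
class OsteotomyPlane:
    """Cut plane: centre point on the centerline at `station` mm from the
    proximal end, normal = long axis tilted by `tilt_a` about the first
    transverse axis and `tilt_z` about the second."""

    point: np.ndarray
    normal: np.ndarray
    station: float
    tilt_a: float
    tilt_z: float
    frame: BoneFrame

    def __post_init__(self):
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be unit length")

    @classmethod
    def from_parameters(
        cls, frame: BoneFrame, point: np.ndarray, station: float, tilt_a: float, tilt_z: float
    ) -> "OsteotomyPlane":
        e_a, e_b, axis = frame.axes.T
        # n = R(e_a, tilt_a) · R(e_b, tilt_z) · axis; in frame coordinates
        # (sin tz, −sin ta cos tz, cos ta cos tz)
        n_local = np.array(
            [
                np.sin(tilt_z),
                -np.sin(tilt_a) * np.cos(tilt_z),
                np.cos(tilt_a) * np.cos(tilt_z),
            ]
        )
        n = frame.axes @ n_local
        return cls(point=np.asarray(point, float), normal=n, station=float(station),
                   tilt_a=float(tilt_a), tilt_z=float(tilt_z), frame=frame)

    def tilts_in_frame(self, frame: BoneFrame) -> tuple[float, float]:
        """Recover (tilt_a, tilt_z) of this plane's normal in a given frame."""
        n = frame.axes.T @ self.normal
        if n[2] < 0:
            n = -n
        tilt_z = float(np.arcsin(np.clip(n[0], -1.0, 1.0)))
        tilt_a = float(np.arctan2(-n[1], n[2]))
        return tilt_a, tilt_z


@dataclass(frozen=True)
class SearchGrid:
    """Deterministic search grid: centerline stations × transverse tilt pairs.

    Stations step along the middle portion of the bone (the registered joint
    ends are excluded); tilts sweep symmetrically about zero.
    """

    station_step: float = 2.0  # mm
    station_span: tuple[float, float] = (0.2, 0.8)  # fractions of axial extent
    tilt_limit: float = np.deg2rad(45.0)
    tilt_step: float = np.deg2rad(15.0)

    def stations(self, axial_extent: float) -> np.ndarray:
        lo = self.station_span[0] * axial_extent
        hi = self.station_span[1] * axial_extent
        n = int(np.floor((hi - lo) / self.station_step + 1e-9))
        return lo + np.arange(n + 1) * self.station_step

    def tilts(self) -> np.ndarray:
        n = int(np.floor(self.tilt_limit / self.tilt_step + 1e-9))
        return np.arange(-n, n + 1) * self.tilt_step


@dataclass
class CutFragment:
    """One half of a cut bone; `cap_vertices` indexes the cut-face vertices."""

    mesh: SurfaceMesh
    cap_vertices: np.ndarray
    side: str  # "proximal" | "distal"

    def transformed(self, t: RigidTransform) -> "CutFragment":
        return replace(self, mesh=self.mesh.transformed(t))

    @property
    def cap_points(self) -> np.ndarray:
        return self.mesh.vertices[self.cap_vertices]


@dataclass
class PlanningResult:
    """Complete outcome of planning one bone with one segmentation source."""

    plane: OsteotomyPlane
    proximal_fragment: CutFragment
    distal_fragment: CutFragment
    m_prox: RigidTransform
    m_dist: RigidTransform
    realignment: RigidTransform
    objective: float
    wedge_type: str  # "opening" | "closing"
    secondary_plane: OsteotomyPlane | None = None
    secondary_intersects_primary: bool | None = None
    bone: str = ""
    method: str = ""
    overlap_weight: float = 0.0
    n_grid_nodes: int = 0
    #: axial location of the cut on the reconstructed anatomy (mm from the
    #: template's proximal end): the plane centre carried through M_prox and
    #: projected on the template's long axis.  This is the ΔZ a surgeon
    #: uses — the deformed bone's own principal axis is biased by the bend.
    station_template: float | None = None
    template_frame: BoneFrame | None = None


@dataclass(frozen=True)
class PlaneComparison:
    """Difference in osteotomy location (ΔZ) and orientation (ψ) between two plans."""

    delta_z: float  # mm, distal positive
    psi_a: float  # rad, about the first transverse axis
    psi_z: float  # rad, about the second transverse axis


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------


def bone_frame(mesh: SurfaceMesh, proximal_hint: np.ndarray | None = None) -> BoneFrame:
    return BoneFrame.from_mesh(mesh, proximal_hint=proximal_hint)


def _section_centroid(mesh_tm: trimesh.Trimesh, normal: np.ndarray, point: np.ndarray):
    """Area centroid of the planar cross-section polygon (None if empty)."""
    segments = trimesh.intersections.mesh_plane(mesh_tm, normal, point)
    if len(segments) == 0:
        return None
    pts = segments.reshape(-1, 3)
    # order points angularly around their mean in the section plane and
    # apply the polygon (shoelace) centroid; sections are star-shaped
    e_a = pts[0] - pts.mean(axis=0)
    e_a = e_a - (e_a @ normal) * normal
    if np.linalg.norm(e_a) < 1e-12:
        return pts.mean(axis=0)
    e_a /= np.linalg.norm(e_a)
    e_b = np.cross(normal, e_a)
    rel = pts - pts.mean(axis=0)
    u, v = rel @ e_a, rel @ e_b
    order = np.argsort(np.arctan2(v, u))
    u, v = u[order], v[order]
    x1, y1 = u, v
    x2, y2 = np.roll(u, -1), np.roll(v, -1)
    cross = x1 * y2 - x2 * y1
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return pts.mean(axis=0)
    cu = ((x1 + x2) * cross).sum() / (6.0 * area)
    cv = ((y1 + y2) * cross).sum() / (6.0 * area)
    return pts.mean(axis=0) + cu * e_a + cv * e_b


def centerline(
    mesh: SurfaceMesh,
    n_samples: int = 50,
    frame: BoneFrame | None = None,
    stations: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Axial centerline: cross-section area centroids at axial stations.

    Returns ``(stations, points)`` ordered proximal→distal.  Stations whose
    cross-section is empty are skipped; more than 20 % skipped is an error.
    """
    frame = frame or BoneFrame.from_mesh(mesh)
    z = frame.axial_coordinate(mesh.vertices)
    extent = z.max() - z.min()
    transverse = mesh.vertices - np.outer(z, frame.long_axis)
    spread = transverse.std(axis=0).max() * 4.0  # ~ transverse extent
    if extent < 3.0 * max(spread, 1e-9) and stations is None:
        raise ValueError("mesh is not elongated: axial extent < 3× transverse extent")
    if stations is None:
        stations = (np.arange(n_samples) + 0.5) / n_samples * extent  # mm from proximal end
    else:
        stations = np.asarray(stations, float)
    tm = mesh.to_trimesh()
    kept_s, kept_p = [], []
    for s in stations:
        origin = frame.origin + (z.min() + s) * frame.long_axis
        c = _section_centroid(tm, frame.long_axis, origin)
        if c is not None:
            kept_s.append(float(s))
            kept_p.append(c)
    if len(kept_s) < 0.8 * len(stations):
        raise ValueError("more than 20% of centerline stations had empty cross-sections")
    return np.asarray(kept_s), np.asarray(kept_p)


# ---------------------------------------------------------------------------
# cutting
# ---------------------------------------------------------------------------


def _boundary_loops(faces: np.ndarray) -> list[np.ndarray]:
    """Vertex loops of the open boundary (edges referenced by one face)."""
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    key = np.sort(edges, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    boundary = edges[counts[inv] == 1]
    nxt = {int(a): int(b) for a, b in boundary}  # directed boundary edges chain into loops
    loops = []
    seen = set()
    for start in nxt:
        if start in seen:
            continue
        loop = [start]
        seen.add(start)
        cur = nxt[start]
        while cur != start and cur is not None and cur not in seen:
            loop.append(cur)
            seen.add(cur)
            cur = nxt.get(cur)
        if cur == start and len(loop) >= 3:
            loops.append(np.asarray(loop))
    return loops


def _cap(mesh: trimesh.Trimesh) -> tuple[trimesh.Trimesh, np.ndarray]:
    """Close the open boundary loops with centroid fans; return (mesh, cap vertex ids)."""
    faces = np.asarray(mesh.faces)
    verts = np.asarray(mesh.vertices)
    loops = _boundary_loops(faces)
    cap_vertex_ids = []
    new_faces = []
    for loop in loops:
        centre = verts[loop].mean(axis=0)
        cid = len(verts)
        verts = np.vstack([verts, centre])
        cap_vertex_ids.extend(loop.tolist() + [cid])
        a, b = loop, np.roll(loop, -1)
        # following the directed boundary keeps the winding consistent with
        # the open surface
        new_faces.append(np.column_stack([b, a, np.full(len(loop), cid)]))
    if new_faces:
        faces = np.vstack([faces] + new_faces)
    capped = trimesh.Trimesh(verts, faces, process=False)
    if capped.volume < 0:
        trimesh.repair.fix_normals(capped)
    return capped, np.unique(np.asarray(cap_vertex_ids, dtype=np.int64))


def cut_with_plane(mesh: SurfaceMesh, plane: OsteotomyPlane) -> tuple[CutFragment, CutFragment]:
    """Cut a bone into watertight proximal and distal fragments.

    The distal fragment is the side the (distal-pointing) plane normal faces.
    Cut faces are capped by fan-triangulating each intersection loop and the
    cap vertices are tagged for the gap objective.
    """
    tm = mesh.to_trimesh()
    halves = []
    for side, sign in (("proximal", -1.0), ("distal", 1.0)):
        open_half = trimesh.intersections.slice_mesh_plane(
            tm, plane_normal=sign * plane.normal, plane_origin=plane.point, cap=False
        )
        if open_half is None or len(open_half.faces) == 0:
            raise ValueError("plane does not intersect the mesh interior")
        open_half.merge_vertices()  # slicing duplicates vertices along the cut
        capped, cap_ids = _cap(open_half)
        halves.append(CutFragment(SurfaceMesh.from_trimesh(capped, name=f"{mesh.name}:{side}"), cap_ids, side))
    if abs(len(halves[0].mesh.faces) + len(halves[1].mesh.faces) - len(mesh.faces)) == 0 and (
        len(halves[0].cap_vertices) == 0 or len(halves[1].cap_vertices) == 0
    ):
        raise ValueError("plane does not intersect the mesh interior")
    return halves[0], halves[1]


def reconstruct(
    proximal: CutFragment, distal: CutFragment, m_prox: RigidTransform, m_dist: RigidTransform
) -> tuple[CutFragment, CutFragment]:
    """Move each fragment with its saved joint-end registration transform."""
    return proximal.transformed(m_prox), distal.transformed(m_dist)


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def _symmetric_mean_nn(a: np.ndarray, b: np.ndarray) -> float:
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    return float(np.concatenate([d_ab, d_ba]).mean())


def cut_contour(mesh: SurfaceMesh, plane: OsteotomyPlane) -> np.ndarray:
    """Points of the plane∩mesh intersection polygon(s) (the shared cut face)."""
    segments = trimesh.intersections.mesh_plane(mesh.to_trimesh(), plane.normal, plane.point)
    if len(segments) == 0:
        raise ValueError("plane does not intersect the mesh")
    return segments.reshape(-1, 3)


def _contains(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Inside test for a watertight, outward-oriented mesh.

    A point is inside when the vector to its nearest surface point opposes
    that triangle's outward normal (signed nearest-surface distance < 0).
    """
    from .geometry import SurfaceQuery

    q = SurfaceQuery(mesh)
    d, cp, fid = q.query(points)
    normals = q.face_normals(fid)
    return np.einsum("ij,ij->i", np.asarray(points, float) - cp, normals) < 0.0


def _overlap_fraction(prox: SurfaceMesh, dist: SurfaceMesh, contralateral: SurfaceMesh, spacing: float = 1.0) -> float:
    """Fraction of the contralateral volume covered by the reconstructed union."""
    tm_c = contralateral.to_trimesh()
    lo, hi = tm_c.bounds
    grid = [np.arange(lo[i] + spacing / 2, hi[i], spacing) for i in range(3)]
    pts = np.stack(np.meshgrid(*grid, indexing="ij"), axis=-1).reshape(-1, 3)
    inside_c = _contains(contralateral, pts)
    pts = pts[inside_c]
    if len(pts) == 0:
        return 0.0
    covered = _contains(prox, pts) | _contains(dist, pts)
    return float(covered.sum() / inside_c.sum())


def objective(
    recon_prox: CutFragment,
    recon_dist: CutFragment,
    contralateral: SurfaceMesh | None = None,
    overlap_weight: float = 0.0,
) -> float:
    """Planning objective (mm): cut-face gap minus weighted template overlap.

    The gap term is the symmetric mean nearest-neighbour distance between the
    two reconstructed cut-face vertex sets.  With `overlap_weight` > 0 the
    fraction of the contralateral template volume covered by the
    reconstructed fragments is subtracted (scaled by 1 mm), rewarding
    reconstructions that fill the template.
    """
    if len(recon_prox.cap_vertices) == 0 or len(recon_dist.cap_vertices) == 0:
        raise ValueError("fragments carry no cut-face tags")
    value = _symmetric_mean_nn(recon_prox.cap_points, recon_dist.cap_points)
    if overlap_weight > 0.0:
        if contralateral is None:
            raise ValueError("overlap_weight > 0 requires the contralateral mesh")
        value -= overlap_weight * _overlap_fraction(recon_prox.mesh, recon_dist.mesh, contralateral)
    return value


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------


def _grid_nodes(frame: BoneFrame, mesh: SurfaceMesh, grid: SearchGrid):
    z = frame.axial_coordinate(mesh.vertices)
    extent = float(z.max() - z.min())
    stations = grid.stations(extent)
    cl_stations, cl_points = centerline(mesh, frame=frame, stations=stations)
    tilts = grid.tilts()
    nodes = []
    for s, p in zip(cl_stations, cl_points):
        for ta in tilts:
            for tz in tilts:
                nodes.append((float(s), p, float(ta), float(tz)))
    return nodes, extent


def _evaluate_node(mesh_tm, frame, node, m_prox, m_dist):
    s, p, ta, tz = node
    plane = OsteotomyPlane.from_parameters(frame, p, s, ta, tz)
    segments = trimesh.intersections.mesh_plane(mesh_tm, plane.normal, plane.point)
    if len(segments) == 0:
        return None, plane
    contour = segments.reshape(-1, 3)
    gap = _symmetric_mean_nn(m_prox.apply(contour), m_dist.apply(contour))
    return gap, plane


def exhaustive_search(
    deformed: SurfaceMesh,
    contralateral_mirrored: SurfaceMesh,
    m_prox: RigidTransform,
    m_dist: RigidTransform,
    grid: SearchGrid | None = None,
    frame: BoneFrame | None = None,
    overlap_weight: float = 0.0,
    bone: str = "",
    method: str = "",
) -> PlanningResult:
    """Evaluate the objective at every grid node and return the global optimum.

    During the sweep the gap term is evaluated on the plane∩mesh intersection
    contour — the vertex set both cut faces share — which avoids re-cutting
    and capping the mesh at every node; the returned optimum is then cut
    fully.  Ties break deterministically: smaller objective, then smaller
    |station − mid-shaft|, then lexicographic (station, tilt_a, tilt_z).
    """
    grid = grid or SearchGrid()
    frame = frame or BoneFrame.from_mesh(deformed)
    nodes, extent = _grid_nodes(frame, deformed, grid)
    if not nodes:
        raise ValueError("empty search grid")
    tm = deformed.to_trimesh()
    mid = extent / 2.0
    best_key, best_plane, best_obj = None, None, None
    n_valid = 0
    use_overlap = overlap_weight > 0.0
    for node in nodes:
        gap, plane = _evaluate_node(tm, frame, node, m_prox, m_dist)
        if gap is None:
            continue
        n_valid += 1
        obj = gap
        if use_overlap:
            prox, dist = cut_with_plane(deformed, plane)
            rp, rd = reconstruct(prox, dist, m_prox, m_dist)
            obj = objective(rp, rd, contralateral_mirrored, overlap_weight)
        key = (obj, abs(node[0] - mid), node[0], node[2], node[3])
        if best_key is None or key < best_key:
            best_key, best_plane, best_obj = key, plane, obj
    if best_plane is None:
        raise ValueError("no grid node produced a plane intersecting the bone")
    prox, dist = cut_with_plane(deformed, best_plane)
    recon_prox, recon_dist = reconstruct(prox, dist, m_prox, m_dist)
    realignment = relative(m_prox, m_dist)
    wedge = _wedge_type(best_plane, recon_prox, recon_dist, m_prox)
    template_frame = BoneFrame.from_mesh(contralateral_mirrored)
    station_template = float(
        template_frame.axial_coordinate(m_prox.apply(best_plane.point[None]))[0]
    )
    result = PlanningResult(
        plane=best_plane,
        proximal_fragment=recon_prox,
        distal_fragment=recon_dist,
        m_prox=m_prox,
        m_dist=m_dist,
        realignment=realignment,
        objective=float(best_obj),
        wedge_type=wedge,
        bone=bone or deformed.name,
        method=method,
        overlap_weight=overlap_weight,
        n_grid_nodes=n_valid,
        station_template=station_template,
        template_frame=template_frame,
    )
    return secondary_cut(result, deformed)


def _wedge_type(plane: OsteotomyPlane, recon_prox: CutFragment, recon_dist: CutFragment, m_prox: RigidTransform) -> str:
    """Closing iff the reconstructed distal fragment crosses the proximal cut face."""
    point = m_prox.apply(plane.point[None])[0]
    normal = m_prox.apply_vector(plane.normal[None])[0]
    depth = (recon_dist.mesh.vertices - point) @ normal
    return "closing" if depth.min() < -INTERPENETRATION_TOL else "opening"


def secondary_cut(result: PlanningResult, deformed: SurfaceMesh) -> PlanningResult:
    """Derive the second, mated cut of a closing wedge.

    The secondary plane, expressed on the original deformed bone, is the
    primary plane carried through ``M_dist⁻¹ · M_prox`` so that after the
    distal fragment moves it lands exactly on the proximal cut face.  The
    red/green flag reports whether the two cut polygons intersect inside the
    bone (the planes' intersection line crosses the primary cut polygon).
    """
    if result.wedge_type != "closing":
        return replace(result, secondary_plane=None, secondary_intersects_primary=None)
    carry = relative(result.m_dist, result.m_prox)  # = M_dist⁻¹ · M_prox
    point = carry.apply(result.plane.point[None])[0]
    normal = carry.apply_vector(result.plane.normal[None])[0]
    frame = result.plane.frame
    if normal @ frame.long_axis < 0:
        normal = -normal
    station = float(frame.axial_coordinate(point[None])[0])
    secondary = OsteotomyPlane(point=point, normal=normal / np.linalg.norm(normal),
                               station=station, tilt_a=np.nan, tilt_z=np.nan, frame=frame)
    primary_contour = cut_contour(deformed, result.plane)
    signed = (primary_contour - secondary.point) @ secondary.normal
    intersects = bool(signed.min() < -1e-6 and signed.max() > 1e-6)
    return replace(result, secondary_plane=secondary, secondary_intersects_primary=intersects)


# ---------------------------------------------------------------------------
# plane comparison
# ---------------------------------------------------------------------------


def compare_planes(a: PlanningResult, b: PlanningResult, frame: BoneFrame | None = None) -> PlaneComparison:
    """ΔZ and ψ differences between two plans of the same bone.

    ΔZ is the signed axial offset of the plane centres (distal positive),
    measured on the reconstructed anatomy when both plans carry it; ψ are
    the differences of the plane tilts about the two transverse axes of the
    shared bone frame.
    """
    if a.bone and b.bone and a.bone != b.bone:
        raise ValueError(f"plans are for different bones: {a.bone!r} vs {b.bone!r}")
    frame = frame or a.plane.frame
    if a.station_template is not None and b.station_template is not None:
        za, zb = a.station_template, b.station_template
    else:
        za = float(frame.axial_coordinate(a.plane.point[None])[0])
        zb = float(frame.axial_coordinate(b.plane.point[None])[0])
    ta_a, tz_a = a.plane.tilts_in_frame(frame)
    ta_b, tz_b = b.plane.tilts_in_frame(frame)
    return PlaneComparison(delta_z=zb - za, psi_a=ta_b - ta_a, psi_z=tz_b - tz_a)
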