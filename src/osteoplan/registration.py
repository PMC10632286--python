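"""Rigid registration of deformed bones to the mirrored contralateral template.

The deformed bone is first coarsely aligned to the mirrored healthy
contralateral bone (centroid + principal axes, signs disambiguated by
residual, then whole-bone ICP).  Its proximal and distal joint ends are then
isolated as axial fragments and each is registered separately to the
template with point-to-surface ICP, yielding the two transforms
``M_prox`` and ``M_dist`` whose relative motion ``M = M_prox⁻¹ × M_dist``
is the bone realignment.

Everything here is deterministic: all vertices are used as correspondences
(no random subsampling), and the rigid update per ICP iteration is the
closed-form least-squares (Kabsch) solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, SurfaceMesh, SurfaceQuery, principal_axis

__all__ = [
    "JointFragment",
    "RegistrationOutcome",
    "RegistrationError",
    "initial_align",
    "isolate_end_fragment",
    "icp_register",
    "register_joint_ends",
]

MIN_FRAGMENT_VERTICES = 50
DEFAULT_FRACTION = 0.20
DEFAULT_TOL = 1e-4  # mm change in RMS between iterations
DEFAULT_MAX_ITER = 100
GATING_FACTOR = 10.0  # correspondences beyond this × current RMS are outliers


class RegistrationError(RuntimeError):
    pass


@dataclass
class JointFragment:
    """Axial end fragment of a bone, the moving surface of one ICP run."""

    mesh: SurfaceMesh
    end: str  # "proximal" | "distal"
    source_bone: str
    extent_fraction: float

    def __post_init__(self):
        if self.end not in ("proximal", "distal"):
            raise ValueError(f"end must be proximal|distal, got {self.end!r}")
        if not (0.0 < self.extent_fraction <= 0.5):
            raise ValueError("extent_fraction must lie in (0, 0.5]")
        if self.mesh.n_vertices < MIN_FRAGMENT_VERTICES:
            raise ValueError(
                f"fragment has {self.mesh.n_vertices} vertices (< {MIN_FRAGMENT_VERTICES}); "
                "use a larger extent fraction"
            )


@dataclass
class RegistrationOutcome:
    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    rms_history: tuple = ()


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid transform mapping moving → fixed."""
    mc, fc = moving.mean(axis=0), fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform.from_rotation_translation(r, fc - r @ mc)


def icp_register(
    moving: JointFragment | SurfaceMesh,
    fixed: SurfaceMesh,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    initial: RigidTransform | None = None,
    rel_tol: float = 0.0,
) -> RegistrationOutcome:
    """Point-to-surface ICP of a moving fragment onto a fixed surface.

    Each iteration projects every moving vertex to its nearest point on the
    fixed surface, discards gross outliers (beyond ``GATING_FACTOR`` × the
    current RMS), and applies the closed-form rigid update.  Iteration stops
    when the RMS change drops below `tol` or `max_iter` is reached.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be positive")
    mesh = moving.mesh if isinstance(moving, JointFragment) else moving
    query = SurfaceQuery(fixed)
    transform = RigidTransform.identity() if initial is None else initial
    pts0 = mesh.vertices

    def evaluate(t: RigidTransform):
        pts = t.apply(pts0)
        dists, targets, fids = query.query(pts)
        rms = float(np.sqrt(np.mean(dists**2)))
        return rms, pts, dists, targets, fids

    rms, pts, dists, targets, fids = evaluate(transform)
    history = [rms]
    converged = False
    for _ in range(1, max_iter + 1):
        keep = dists <= max(GATING_FACTOR * max(rms, 1e-12), 1e-9)
        if not keep.any():
            raise RegistrationError("no usable correspondences: surfaces are too far apart")
        # candidate updates: closed-form point-to-point (large-basin) and,
        # once the coarse phase has slowed, linearized point-to-plane (fast
        # near convergence); keep whichever lowers the residual more — the
        # residual is monotone by construction
        candidates = [_kabsch(pts[keep], targets[keep])]
        warmed = len(history) >= 2 and (history[-2] - history[-1]) < 0.25 * history[-1]
        if warmed:
            normals = query.face_normals(fids[keep])
            candidates.append(_point_to_plane_step(pts[keep], targets[keep], normals))
        best = None
        for upd in candidates:
            cand_t = RigidTransform(upd.matrix @ transform.matrix)
            cand_eval = evaluate(cand_t)
            if best is None or cand_eval[0] < best[1][0]:
                best = (cand_t, cand_eval)
        new_rms = best[1][0]
        stop_at = max(tol, rel_tol * rms)  # rel_tol lets a compromise fit
        # (incongruent surfaces) stop once improvements become marginal
        if new_rms >= rms - stop_at:
            if new_rms < rms:  # accept the final microscopic improvement
                transform = best[0]
                rms, pts, dists, targets, fids = best[1]
                history.append(rms)
            converged = True
            break
        transform = best[0]
        rms, pts, dists, targets, fids = best[1]
        history.append(rms)
    return RegistrationOutcome(
        transform=transform,
        rms_residual=history[-1],
        iterations=len(history),
        converged=converged,
        rms_history=tuple(history),
    )


def _point_to_plane_step(points: np.ndarray, targets: np.ndarray, normals: np.ndarray) -> RigidTransform:
    """Linearized point-to-plane update: minimize Σ (n·(p + ω×p + t − q))²."""
    a = np.hstack([np.cross(points, normals), normals])  # (m, 6): [ω, t] coefficients
    b = -np.einsum("ij,ij->i", points - targets, normals)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    omega, t = sol[:3], sol[3:]
    angle = np.linalg.norm(omega)
    if angle < 1e-15:
        return RigidTransform.from_rotation_translation(np.eye(3), t)
    axis = omega / angle
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    r = np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)
    return RigidTransform.from_rotation_translation(r, t)


N_SPIN_CANDIDATES = 12  # coarse rotational scan about the long axis


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest rotation taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    c = float(a @ b)
    if c < -1.0 + 1e-12:  # antiparallel: rotate pi about any perpendicular
        perp = np.eye(3)[int(np.argmin(np.abs(a)))]
        perp = perp - (perp @ a) * a
        perp /= np.linalg.norm(perp)
        k = np.array([[0, -perp[2], perp[1]], [perp[2], 0, -perp[0]], [-perp[1], perp[0], 0]])
        return np.eye(3) + 2.0 * (k @ k)
    k = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + k + k @ k / (1.0 + c)


def initial_align(
    moving: SurfaceMesh,
    fixed: SurfaceMesh,
    refine: bool = True,
    moving_proximal_hint: np.ndarray = (0.0, 0.0, 1.0),
    fixed_proximal_hint: np.ndarray = (0.0, 0.0, 1.0),
) -> RigidTransform:
    """Coarse deterministic alignment of two whole bones.

    Centroids are matched and the long (first principal) axes superposed,
    with the axis sign fixed by the caller-declared proximal→distal hints
    (the end-for-end orientation of a bone is metadata, not geometry).
    Because the transverse principal directions of a twisted shaft are
    unstable, the spin about the long axis is resolved by scanning
    ``N_SPIN_CANDIDATES`` rotations scored by trimmed nearest-neighbour
    residual, mini-ICP-refining the best few, and keeping the winner.  A
    whole-bone ICP refinement follows unless `refine` is False.
    """

    def major_axis(mesh, hint):
        v = mesh.vertices - mesh.vertices.mean(axis=0)
        evals, evecs = np.linalg.eigh(v.T @ v / len(v))
        if evals[2] < 1e-12:
            raise ValueError("degenerate principal axes")
        axis = evecs[:, 2]
        return axis if axis @ np.asarray(hint, float) >= 0 else -axis

    am = major_axis(moving, moving_proximal_hint)
    af = major_axis(fixed, fixed_proximal_hint)
    cm = moving.vertices.mean(axis=0)
    cf = fixed.vertices.mean(axis=0)
    tree = cKDTree(fixed.vertices)

    def trimmed(d: np.ndarray) -> float:
        # judge a pose by its best-matching half: the congruent part of the
        # bones should match almost exactly, so a deformity elsewhere cannot
        # outvote the match
        return float(np.mean(np.sort(d)[: max(1, len(d) // 2)]))

    coarse = []
    base = _minimal_rotation(am, af)
    for i in range(N_SPIN_CANDIDATES):
        theta = 2.0 * np.pi * i / N_SPIN_CANDIDATES
        spin = RigidTransform.from_axis_angle(af, theta).rotation
        r = spin @ base
        cand = RigidTransform.from_rotation_translation(r, cf - r @ cm)
        score = trimmed(tree.query(cand.apply(moving.vertices))[0])
        coarse.append((score, len(coarse), cand))
    coarse.sort(key=lambda item: item[:2])
    # mini-ICP the best coarse poses on a subsample and re-score: the coarse
    # score alone can prefer an upside-down pose for strongly bent bones
    sub = SurfaceMesh(moving.vertices[::3], np.empty((0, 3), dtype=np.int64))
    best = None
    for score, _, cand in coarse[:4]:
        try:
            mini = icp_register(sub, fixed, max_iter=10, tol=1e-3, initial=cand)
        except RegistrationError:
            continue
        d = tree.query(mini.transform.apply(sub.vertices))[0]
        key = trimmed(d)
        if best is None or key < best[0]:
            best = (key, mini.transform)
    if best is None:
        raise RegistrationError("initial alignment failed: no candidate produced correspondences")
    transform = best[1]
    if refine:
        outcome = icp_register(moving, fixed, max_iter=40, tol=1e-6, rel_tol=1e-3, initial=transform)
        transform = outcome.transform
    return transform


def isolate_end_fragment(
    mesh: SurfaceMesh,
    end: str,
    fraction: float = DEFAULT_FRACTION,
    proximal_hint: np.ndarray | None = None,
) -> JointFragment:
    """Submesh of the faces in the terminal axial band of a bone.

    Faces whose centroid projects onto the principal axis within `fraction`
    of the bone's axial extent, measured from the chosen end, are kept.
    """
    if not (0.0 < fraction <= 0.5):
        raise ValueError(f"fraction must lie in (0, 0.5], got {fraction}")
    axis, _ = principal_axis(mesh, proximal_hint=proximal_hint)
    proj = mesh.vertices @ axis
    lo, hi = proj.min(), proj.max()
    extent = hi - lo
    centroids = mesh.vertices[mesh.faces].mean(axis=1) @ axis
    t = (centroids - lo) / extent
    if end == "proximal":
        keep = t <= fraction
    elif end == "distal":
        keep = t >= 1.0 - fraction
    else:
        raise ValueError(f"end must be proximal|distal, got {end!r}")
    faces = mesh.faces[keep]
    used = np.unique(faces)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[used] = np.arange(len(used))
    sub = SurfaceMesh(mesh.vertices[used], remap[faces], name=f"{mesh.name}:{end}")
    try:
        return JointFragment(sub, end=end, source_bone=mesh.name, extent_fraction=fraction)
    except ValueError as exc:
        raise ValueError(str(exc)) from None


SPIN_STARTS_DEG = tuple(np.arange(12) * 30.0)  # full turn: the pre-alignment
# of a bent bone cannot pin the spin, but a joint-end fragment can
SHIFT_STARTS_MM = (-4.0, 0.0, 4.0)


def _multistart_fragment_icp(
    frag: JointFragment,
    fixed: SurfaceMesh,
    axis_point: np.ndarray,
    axis_dir: np.ndarray,
    max_iter: int,
    tol: float,
) -> RegistrationOutcome:
    """Fragment ICP from a deterministic grid of starts.

    A whole-bone pre-alignment of a deformed bone cannot resolve the spin
    about the long axis or small axial slides — the deformity mismatch
    swamps those signals — but the joint-end fragment is congruent with its
    template counterpart, so the correct basin reaches a near-zero residual
    that every wrong basin misses.  Mini-ICP from a grid of spin ×
    axial-shift starts (scored on a vertex subsample) finds that basin; the
    best start is then refined at full resolution.
    """
    sub = SurfaceMesh(frag.mesh.vertices[::3], np.empty((0, 3), dtype=np.int64))
    query = SurfaceQuery(fixed)

    # baseline: stay where the whole-bone pre-alignment put the fragment
    try:
        base = icp_register(sub, fixed, max_iter=15, tol=1e-4, initial=RigidTransform.identity())
        best = (base.rms_residual, base.transform)
    except RegistrationError:
        best = None

    if best is None or best[0] > 0.02:  # pre-aligned basin is not clean; scan
        coarse_sub = SurfaceMesh(frag.mesh.vertices[::6], np.empty((0, 3), dtype=np.int64))
        stage_a = []
        for th in np.deg2rad(SPIN_STARTS_DEG):
            spin = RigidTransform.from_axis_angle(axis_dir, th, point=axis_point)
            for sh in SHIFT_STARTS_MM:
                init = RigidTransform.from_rotation_translation(
                    spin.rotation, spin.translation + sh * axis_dir
                )
                try:
                    quick = icp_register(coarse_sub, fixed, max_iter=4, tol=1e-3, initial=init)
                except RegistrationError:
                    continue
                stage_a.append((quick.rms_residual, len(stage_a), quick.transform))
        stage_a.sort(key=lambda item: item[:2])
        # an alternative start must beat the baseline decisively: near the
        # noise floor the mini-ICP scores of all spins are within a few
        # percent of each other and choosing among them would be arbitrary
        margin = 0.9
        for _, _, init in stage_a[:6]:
            try:
                mini = icp_register(sub, fixed, max_iter=10, tol=1e-4, initial=init)
            except RegistrationError:
                continue
            if best is None:
                best = (mini.rms_residual, mini.transform)
            elif mini.rms_residual < margin * best[0]:
                best = (mini.rms_residual, mini.transform)
            if best[0] < 0.02:  # unambiguously the congruent basin
                break
    if best is None:
        raise RegistrationError("no multistart candidate produced correspondences")
    return icp_register(frag, fixed, max_iter=max_iter, tol=tol, initial=best[1])


def register_joint_ends(
    deformed: SurfaceMesh,
    contralateral_mirrored: SurfaceMesh,
    fraction: float = DEFAULT_FRACTION,
    proximal_hint: np.ndarray | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
) -> tuple[RegistrationOutcome, RegistrationOutcome]:
    """Register the two joint-end fragments of the deformed bone to the template.

    Inputs are expected to be pre-aligned by :func:`initial_align`.  Returns
    the proximal and distal outcomes; their transforms are ``M_prox`` and
    ``M_dist``.
    """
    axis_dir, axis_anchor = principal_axis(contralateral_mirrored, proximal_hint=proximal_hint)
    outcomes = []
    for end in ("proximal", "distal"):
        frag = isolate_end_fragment(deformed, end, fraction, proximal_hint=proximal_hint)
        try:
            outcomes.append(
                _multistart_fragment_icp(
                    frag, contralateral_mirrored, axis_anchor, axis_dir, max_iter=max_iter, tol=tol
                )
            )
        except RegistrationError as exc:
            raise RegistrationError(f"{end} fragment: {exc}") from exc
    return outcomes[0], outcomes[1]
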