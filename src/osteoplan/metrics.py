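"""Segmentation agreement metrics and relative cartilage volume.

Implements the four agreement metrics used to compare bone segmentations
from different modalities — Dice similarity coefficient (DSC), mean absolute
surface distance (MASD), Hausdorff distance (HD) and its 95th-percentile
variant (HD95) — plus the relative cartilage volume (RCV, cartilage volume
over bone volume).

Both a voxel path (boundary-voxel centres of label masks) and a mesh path
(per-vertex nearest-triangle distances) are provided, because segmentations
may arrive as label volumes or as reconstructed surface models; reports
record which path produced a number.

MASD is the symmetric mean over the union of both directed distance
multisets (the average symmetric surface distance of Taha & Hanbury); HD95
uses linearly interpolated percentiles of that union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import LabelVolume, SurfaceMesh, SurfaceQuery, mesh_volume

__all__ = [
    "AgreementReport",
    "CartilageStats",
    "dice",
    "surface_distances",
    "masd",
    "hausdorff",
    "hd95",
    "agreement_report",
    "relative_cartilage_volume",
]


@dataclass(frozen=True)
class AgreementReport:
    """The four agreement metrics for one pair of segmentations."""

    dsc: float
    masd: float
    hd: float
    hd95: float
    source: str = "voxel"  # which path produced the numbers: "voxel" | "mesh"

    def __post_init__(self):
        if not (0.0 <= self.dsc <= 1.0):
            raise ValueError("DSC must lie in [0, 1]")
        if not (0.0 <= self.masd <= self.hd + 1e-12 and self.hd95 <= self.hd + 1e-12):
            raise ValueError("distance metrics must satisfy 0 <= masd <= hd and hd95 <= hd")


@dataclass(frozen=True)
class CartilageStats:
    """Cartilage and bone volumes (mm³) and their ratio for one bone."""

    rcv: float
    bone_volume: float
    cartilage_volume: float
    bone: str = ""


def _as_mask(a) -> np.ndarray:
    if isinstance(a, LabelVolume):
        return a.array != 0
    return np.asarray(a, dtype=bool)


def _check_grids(a, b) -> None:
    if isinstance(a, LabelVolume) and isinstance(b, LabelVolume) and not a.same_grid(b):
        raise ValueError("label volumes are on different grids (shape/spacing/origin)")
    ma, mb = _as_mask(a), _as_mask(b)
    if ma.shape != mb.shape:
        raise ValueError(f"mask shapes differ: {ma.shape} vs {mb.shape}")


def dice(a, b) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A| + |B|) on voxel masks.

    Both masks empty is perfect agreement on nothing (1.0); exactly one
    empty is complete disagreement (0.0).
    """
    _check_grids(a, b)
    ma, mb = _as_mask(a), _as_mask(b)
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def _boundary_points(mask: np.ndarray, spacing: float, origin: np.ndarray) -> np.ndarray:
    """Physical centres of the boundary voxels (mask minus its 6-erosion)."""
    er = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    idx = np.argwhere(mask & ~er)
    return idx * spacing + origin


def surface_distances(a, b) -> tuple[np.ndarray, np.ndarray]:
    """Directed surface-distance multisets (a→b, b→a), in mm.

    Mask inputs: distances between boundary-voxel centres.  Mesh inputs:
    per-vertex distances to the nearest triangle of the other mesh.
    """
    if isinstance(a, SurfaceMesh) and isinstance(b, SurfaceMesh):
        if a.n_vertices == 0 or b.n_vertices == 0:
            raise ValueError("empty surface")
        d_ab = SurfaceQuery(b).distances(a.vertices)
        d_ba = SurfaceQuery(a).distances(b.vertices)
        return d_ab, d_ba

    _check_grids(a, b)
    spacing = a.spacing if isinstance(a, LabelVolume) else 1.0
    origin = a.origin if isinstance(a, LabelVolume) else np.zeros(3)
    pa = _boundary_points(_as_mask(a), spacing, origin)
    pb = _boundary_points(_as_mask(b), spacing, origin)
    if len(pa) == 0 or len(pb) == 0:
        raise ValueError("empty surface: one of the masks has no foreground")
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return d_ab, d_ba


def _union(a, b) -> np.ndarray:
    d_ab, d_ba = surface_distances(a, b)
    return np.concatenate([d_ab, d_ba])


def masd(a, b) -> float:
    """Mean absolute surface distance: mean of both directed multisets."""
    return float(_union(a, b).mean())


def hausdorff(a, b) -> float:
    """Hausdorff distance: maximum over both directed multisets."""
    return float(_union(a, b).max())


def hd95(a, b) -> float:
    """95th percentile (linear interpolation) over both directed multisets."""
    return float(np.percentile(_union(a, b), 95.0, method="linear"))


def agreement_report(a, b, mesh_pair_for_distances: tuple[SurfaceMesh, SurfaceMesh] | None = None) -> AgreementReport:
    """All four metrics for one pair of segmentations.

    DSC is always voxel-based (mesh inputs are not accepted for it here);
    distances are computed from `mesh_pair_for_distances` when given —
    matching a workflow where models are compared as surfaces after initial
    alignment — and from the masks otherwise.
    """
    d = dice(a, b)
    if mesh_pair_for_distances is not None:
        u = _union(*mesh_pair_for_distances)
        src = "mesh"
    else:
        u = _union(a, b)
        src = "voxel"
    return AgreementReport(
        dsc=d,
        masd=float(u.mean()),
        hd=float(u.max()),
        hd95=float(np.percentile(u, 95.0, method="linear")),
        source=src,
    )


def relative_cartilage_volume(bone_mesh: SurfaceMesh, cartilage_mesh: SurfaceMesh | None, bone: str = "") -> CartilageStats:
    """RCV = cartilage volume / bone volume, from watertight meshes.

    `cartilage_mesh` may be None or empty (no cartilage → RCV 0).
    """
    bv = mesh_volume(bone_mesh)
    if cartilage_mesh is None or cartilage_mesh.n_vertices == 0:
        cv = 0.0
    else:
        cv = mesh_volume(cartilage_mesh)
    return CartilageStats(rcv=cv / bv, bone_volume=bv, cartilage_volume=cv, bone=bone)
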