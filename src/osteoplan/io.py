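"""Readers and writers: NIfTI label volumes, STL/PLY meshes, JSON transforms."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh
from scipy import ndimage

from .geometry import LabelVolume, RigidTransform, SurfaceMesh

__all__ = [
    "read_label_volume",
    "write_label_volume",
    "read_mesh",
    "write_mesh",
    "read_transform",
    "write_transform",
]

DEFAULT_LABEL_MAP = {"radius": 1, "cartilage": 2, "ulna": 3}


def _resample_grid_isotropic(arr: np.ndarray, spacings: np.ndarray, target: float) -> np.ndarray:
    """Per-label indicator resampling of a possibly anisotropic grid."""
    scale = spacings / target
    new_shape = np.maximum(2, np.round(np.array(arr.shape) * scale).astype(int))
    # half-voxel offset per axis keeps the field of view (and hence label
    # volumes) intact through the grid change
    grids = [
        (0.5 * (target - spacings[i]) + np.arange(n) * target) / spacings[i]
        for i, n in enumerate(new_shape)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = np.zeros(tuple(new_shape), dtype=arr.dtype)
    best = np.full(tuple(new_shape), 0.5)
    for code in np.unique(arr):
        if code == 0:
            continue
        w = ndimage.map_coordinates((arr == code).astype(float), coords, order=1, cval=0.0)
        take = w > best
        out[take] = code
        best[take] = w[take]
    return out


def read_label_volume(path, label_map: dict | None = None, target_spacing: float = 0.5) -> LabelVolume:
    """Read a NIfTI label volume; anisotropic inputs are resampled (with a warning).

    Non-integer data is rejected: this reader is for segmentations, not images.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: non-integer data; expected a label volume")
        data = np.round(data).astype(np.int16)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        warnings.warn(
            f"{path}: anisotropic spacing {tuple(zooms)}; resampling to isotropic {target_spacing} mm"
        )
        data = _resample_grid_isotropic(data, zooms, target_spacing)
        spacing = float(target_spacing)
    else:
        spacing = float(zooms[0])
    lm = label_map or {
        name: code for name, code in DEFAULT_LABEL_MAP.items() if code in np.unique(data)
    }
    return LabelVolume(data.astype(np.int16), spacing, origin, lm)


def write_label_volume(vol: LabelVolume, path) -> None:
    affine = np.diag([vol.spacing] * 3 + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.array.astype(np.int16), affine), str(path))


def read_mesh(path, name: str = "") -> SurfaceMesh:
    """Read an STL or PLY surface mesh (units assumed mm)."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        raise ValueError(f"mesh file {path} is missing or empty")
    tm = trimesh.load(str(path), force="mesh", process=True)
    if tm is None or len(tm.faces) == 0:
        raise ValueError(f"mesh file {path} contains no faces")
    return SurfaceMesh.from_trimesh(tm, name=name or path.stem)


def write_mesh(mesh: SurfaceMesh, path) -> None:
    mesh.to_trimesh().export(str(path))


def read_transform(path) -> RigidTransform:
    with open(path) as fh:
        data = json.load(fh)
    return RigidTransform(np.asarray(data["matrix"], dtype=float))


def write_transform(t: RigidTransform, path, **metadata) -> None:
    payload = {"matrix": t.matrix.tolist(), **metadata}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
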