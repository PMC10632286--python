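"""End-to-end planning pipeline: segmentation → meshes → registration → plane search.

`plan_case` runs the full workflow for one bone and one segmentation source;
`run_pipeline` wraps it with file I/O and artifact writing for the CLI.
All configuration is carried in :class:`PipelineConfig` and echoed into
every report, so a run is reproducible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as opio
from .geometry import (
    LabelVolume,
    SurfaceMesh,
    decompose_euler,
    mesh_from_labels,
    mirror_sagittal,
    resample_isotropic,
)
from .planner import BoneFrame, PlanningResult, SearchGrid, exhaustive_search
from .registration import initial_align, register_joint_ends

__all__ = ["PipelineConfig", "CaseBundle", "plan_case", "mesh_for_method", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the workflow, with its default."""

    fragment_fraction: float = 0.20  # axial fraction isolated at each joint end
    icp_tol: float = 1e-4  # mm RMS change convergence threshold
    icp_max_iter: int = 100
    overlap_weight: float = 0.0  # 0 → pure cut-face gap objective
    station_step: float = 2.0  # mm
    station_span: tuple = (0.2, 0.8)
    tilt_limit_deg: float = 45.0
    tilt_step_deg: float = 15.0
    planning_spacing: float = 1.25  # mm; meshing resolution for planning
    proximal_hint: tuple = (0.0, 0.0, 1.0)  # proximal→distal direction metadata

    def grid(self) -> SearchGrid:
        return SearchGrid(
            station_step=self.station_step,
            station_span=tuple(self.station_span),
            tilt_limit=np.deg2rad(self.tilt_limit_deg),
            tilt_step=np.deg2rad(self.tilt_step_deg),
        )


@dataclass
class CaseBundle:
    """File-based inputs of one planning run."""

    deformed: Path
    contralateral: Path
    method: str = "CTb"  # CTb | MRb | MRbc
    bone: str = "radius"
    contralateral_is_mirrored: bool = False
    output_dir: Path | None = None

    def __post_init__(self):
        if self.method not in ("CTb", "MRb", "MRbc"):
            raise ValueError(f"method must be CTb|MRb|MRbc, got {self.method!r}")
        for p in (self.deformed, self.contralateral):
            if not Path(p).exists():
                raise FileNotFoundError(f"input file missing: {p}")


def mesh_for_method(vol: LabelVolume, method: str, config: PipelineConfig, name: str = "") -> SurfaceMesh:
    """Planning surface for one segmentation source.

    Bone-only sources mesh the bone label; the bone+cartilage source meshes
    the union of bone and cartilage, the composite surface both sides share.
    Volumes are resampled to the (coarser) planning spacing first so mesh
    density stays tractable.
    """
    work = vol
    if method == "MRbc" and "cartilage" in vol.label_map:
        bone_code = vol.label_map.get("radius", 1)
        arr = np.isin(vol.array, [bone_code, vol.label_map["cartilage"]]).astype(np.int16)
        work = LabelVolume(arr, vol.spacing, vol.origin.copy(), {"radius": 1})
    if config.planning_spacing and config.planning_spacing > work.spacing:
        work = resample_isotropic(work, config.planning_spacing)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # stray voxels from noise are expected
        return mesh_from_labels(
            work,
            "radius" if "radius" in work.label_map else next(iter(work.label_map)),
            smooth_sigma=1.0,
        )


def plan_variant(case, method: str, config: PipelineConfig | None = None):
    """Plan one segmentation variant of a synthetic case, both sides matched.

    The deformed side uses the variant's label volume; the healthy side uses
    the corresponding representation (bone, or bone+cartilage for the
    composite variant), mirrored to serve as the contralateral template.
    """
    config = config or PipelineConfig()
    deformed = mesh_for_method(case.volumes[method], method, config, name="radius")
    key = "bone_cartilage" if method == "MRbc" else "bone"
    if case.healthy_volumes:
        healthy_rep = mesh_for_method(
            case.healthy_volumes[key], method, config, name="radius-contralateral"
        )
        contralateral = mirror_sagittal(healthy_rep)
    else:
        contralateral = case.contralateral_mesh
    return plan_case(deformed, contralateral, config=config, method=method, bone="radius")


def plan_case(
    deformed: SurfaceMesh,
    contralateral: SurfaceMesh,
    config: PipelineConfig | None = None,
    mirror_contralateral: bool = True,
    method: str = "",
    bone: str = "",
) -> tuple[PlanningResult, dict]:
    """Run steps 1–5 for one bone: align, register joint ends, search the plane.

    Returns the planning result and a provenance dictionary (registration
    residuals, iterations, effective configuration).
    """
    config = config or PipelineConfig()
    hint = np.asarray(config.proximal_hint, float)
    template = mirror_sagittal(contralateral) if mirror_contralateral else contralateral

    pre = initial_align(deformed, template, moving_proximal_hint=hint, fixed_proximal_hint=hint)
    aligned = deformed.transformed(pre)

    prox_out, dist_out = register_joint_ends(
        aligned,
        template,
        fraction=config.fragment_fraction,
        proximal_hint=hint,
        max_iter=config.icp_max_iter,
        tol=config.icp_tol,
    )
    frame = BoneFrame.from_mesh(aligned, proximal_hint=hint)
    result = exhaustive_search(
        aligned,
        template,
        prox_out.transform,
        dist_out.transform,
        grid=config.grid(),
        frame=frame,
        overlap_weight=config.overlap_weight,
        bone=bone or deformed.name,
        method=method,
    )
    provenance = {
        "config": dataclasses.asdict(config),
        "initial_alignment": pre.matrix.tolist(),
        "registration": {
            end: {
                "rms_residual": out.rms_residual,
                "iterations": out.iterations,
                "converged": out.converged,
                "fraction": config.fragment_fraction,
            }
            for end, out in (("proximal", prox_out), ("distal", dist_out))
        },
    }
    return result, provenance


def result_record(result: PlanningResult, provenance: dict | None = None) -> dict:
    """JSON-serializable report of one planning result."""
    d = decompose_euler(result.realignment)
    rec = {
        "bone": result.bone,
        "method": result.method,
        "objective_mm": result.objective,
        "overlap_weight": result.overlap_weight,
        "wedge_type": result.wedge_type,
        "n_grid_nodes": result.n_grid_nodes,
        "plane": {
            "point": result.plane.point.tolist(),
            "normal": result.plane.normal.tolist(),
            "station_mm": result.plane.station,
            "station_reconstructed_mm": result.station_template,
            "tilt_a_rad": result.plane.tilt_a,
            "tilt_z_rad": result.plane.tilt_z,
        },
        "realignment": {
            "matrix": result.realignment.matrix.tolist(),
            "dx": d.dx, "dy": d.dy, "dz": d.dz,
            "phi_x": d.phi_x, "phi_y": d.phi_y, "phi_z": d.phi_z,
            "T_mm": d.T, "R_rad": d.R,
        },
        "secondary_cut": None,
    }
    if result.secondary_plane is not None:
        rec["secondary_cut"] = {
            "point": result.secondary_plane.point.tolist(),
            "normal": result.secondary_plane.normal.tolist(),
            "intersects_primary": result.secondary_intersects_primary,
        }
    if provenance:
        rec["provenance"] = provenance
    return rec


def run_pipeline(bundle: CaseBundle, config: PipelineConfig | None = None) -> dict:
    """File-in, file-out planning run; returns the report dictionary.

    Writes fragment meshes (STL), transforms (JSON) and the report (JSON)
    into the bundle's output directory when one is given.  Any stage error
    propagates with a stage label; artifacts written before the failure are
    retained.
    """
    config = config or PipelineConfig()

    def _load(path: Path, tag: str) -> SurfaceMesh:
        path = Path(path)
        try:
            if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
                vol = opio.read_label_volume(path)
                return mesh_for_method(vol, bundle.method, config, name=tag)
            return opio.read_mesh(path, name=tag)
        except Exception as exc:
            raise RuntimeError(f"stage 0 (load {tag}): {exc}") from exc

    deformed = _load(bundle.deformed, bundle.bone)
    contralateral = _load(bundle.contralateral, f"{bundle.bone}-contralateral")

    result, provenance = plan_case(
        deformed,
        contralateral,
        config=config,
        mirror_contralateral=not bundle.contralateral_is_mirrored,
        method=bundle.method,
        bone=bundle.bone,
    )
    report = result_record(result, provenance)
    if bundle.output_dir is not None:
        out = Path(bundle.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        prefix = f"{bundle.bone}_{bundle.method}"
        opio.write_mesh(result.proximal_fragment.mesh, out / f"{prefix}_proximal.stl")
        opio.write_mesh(result.distal_fragment.mesh, out / f"{prefix}_distal.stl")
        opio.write_transform(result.m_prox, out / f"{prefix}_m_prox.json", end="proximal")
        opio.write_transform(result.m_dist, out / f"{prefix}_m_dist.json", end="distal")
        opio.write_transform(result.realignment, out / f"{prefix}_realignment.json")
        with open(out / f"{prefix}_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
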