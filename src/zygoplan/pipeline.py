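"""Run configuration, orchestration and reporting for the planning workflow.

A run is a pure function of (inputs, config): the global seed fans out
deterministically to per-stage seeds, every defaulted parameter is echoed in
the report, and all output files are listed with checksums, so a run can be
reconstructed from its report alone.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from zygoplan.evaluation import compare_meshes, extract_outer_shell, write_heatmap
from zygoplan.geometry import apply_transform, write_mesh
from zygoplan.phantom import (
    PhantomParams,
    default_hole_requests,
    generate_phantom,
    rasterize,
    simulate_execution,
)
from zygoplan.planning import make_plan, reposition, verify_plan
from zygoplan.registration import recover_malunion_alignment
from zygoplan.segmentation import extract_surface, seeded_segment

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    cranium_semi_axes: tuple[float, float, float] = (40.0, 50.0, 45.0)
    zygoma_radius_mm: float = Field(14.0, gt=0)
    malunion_translation_mm: tuple[float, float, float] = (-5.0, -2.0, 0.0)
    malunion_rotation_deg: float = 8.0
    vertex_noise_mm: float = Field(0.0, ge=0)
    mesh_resolution_mm: float = Field(1.25, gt=0)
    soft_tissue_thickness_mm: float = Field(6.0, gt=0)


class SegmentationConfig(_Strict):
    enabled: bool = True
    voxel_spacing_mm: float = Field(0.5, gt=0)
    threshold_hu: float = 300.0


class IcpConfig(_Strict):
    max_iter: int = Field(100, ge=1)
    tol_mm: float = Field(1e-4, gt=0)
    trim_fraction: float = Field(0.1, ge=0, lt=1)


class RegistrationConfig(_Strict):
    displaced_side: Literal["left", "right"] = "right"
    run_icp: bool = True
    icp: IcpConfig = IcpConfig()


class PlanningConfig(_Strict):
    n_moving_holes: int = Field(3, ge=3)
    n_stable_holes: int = Field(3, ge=3)
    hole_diameter_mm: float = Field(2.0, gt=0)
    footprint_radius_mm: float = Field(8.0, gt=0)
    guide_thickness_mm: float = Field(2.0, gt=0)
    build_guides: bool = True


class SimulateConfig(_Strict):
    exec_rot_sigma_deg: float = Field(0.0, ge=0)
    exec_trans_sigma_mm: float = Field(0.0, ge=0)


class EvaluationConfig(_Strict):
    samples_per_mm2: float = Field(10.0, gt=0)
    bin_width_mm: float = Field(0.25, gt=0)
    write_heatmaps: bool = True


class RunConfig(_Strict):
    """Schema-validated pipeline configuration (YAML; unknown keys rejected)."""

    version: int = 1
    seed: int = Field(0, ge=0)
    output_dir: str = "zygoplan_run"
    phantom: PhantomConfig = PhantomConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    registration: RegistrationConfig = RegistrationConfig()
    planning: PlanningConfig = PlanningConfig()
    simulate: SimulateConfig = SimulateConfig()
    evaluation: EvaluationConfig = EvaluationConfig()


def _suggest(bad_key: str, model: type[BaseModel]) -> str:
    candidates = {name: name for name in model.model_fields}
    if model is RunConfig:  # also search nested sections for a close match
        for section, sub in _SECTION_MODELS.items():
            for name in sub.model_fields:
                candidates[name] = f"{section}.{name}"
    close = difflib.get_close_matches(bad_key, candidates.keys(), n=1, cutoff=0.7)
    return f"; did you mean {candidates[close[0]]!r}?" if close else ""


_SECTION_MODELS = {
    "phantom": PhantomConfig,
    "segmentation": SegmentationConfig,
    "registration": RegistrationConfig,
    "planning": PlanningConfig,
    "simulate": SimulateConfig,
    "evaluation": EvaluationConfig,
}


def validate_config(raw: str | dict) -> RunConfig:
    """Parse, default and schema-check a YAML config document.

    Unknown keys are rejected with a close-match suggestion; every defaulted
    parameter is logged so the effective configuration is reconstructable.
    """
    doc = yaml.safe_load(raw) if isinstance(raw, str) else raw
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    try:
        cfg = RunConfig(**doc)
    except ValidationError as err:
        msgs = []
        for e in err.errors():
            path = ".".join(str(p) for p in e["loc"])
            msg = f"{path}: {e['msg']}"
            if e["type"] == "extra_forbidden":
                parent: type[BaseModel] = RunConfig
                for part in e["loc"][:-1]:  # walk nested models to the parent
                    field = parent.model_fields.get(str(part))
                    if field is None or not (
                        isinstance(field.annotation, type)
                        and issubclass(field.annotation, BaseModel)
                    ):
                        break
                    parent = field.annotation
                msg += _suggest(str(e["loc"][-1]), parent)
            msgs.append(msg)
        raise ConfigError("invalid config: " + "; ".join(msgs)) from None
    given = set(doc.keys())
    for name in RunConfig.model_fields:
        if name not in given:
            logger.info("config default: %s = %s", name, getattr(cfg, name))
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute phantom -> (rasterize+segment) -> register -> plan -> verify ->
    simulate -> evaluate, writing artifacts and a checksummed report.

    Any stage failure aborts with the stage name in the raised error.
    Returns the report dict (also written to ``report.json``).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.model_dump(), "stages": {}, "manifest": {}}
    files: list[Path] = []

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"][name] = {"status": "running"}
        return report["stages"][name]

    def fail(name, err):
        report["stages"][name]["status"] = "failed"
        report["stages"][name]["error"] = str(err)
        _write_report(report, out, files)
        raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err

    # -- phantom --------------------------------------------------------
    st = stage("phantom")
    try:
        pc = config.phantom
        params = PhantomParams(
            cranium_semi_axes=pc.cranium_semi_axes,
            zygoma_radius_mm=pc.zygoma_radius_mm,
            malunion_translation_mm=pc.malunion_translation_mm,
            malunion_rotation_deg=pc.malunion_rotation_deg,
            vertex_noise_mm=pc.vertex_noise_mm,
            mesh_resolution_mm=pc.mesh_resolution_mm,
            soft_tissue_thickness_mm=pc.soft_tissue_thickness_mm,
            seed=stage_seed(config.seed, "phantom"),
        )
        case = generate_phantom(params)
        case.write(out / "case")
        files += list((out / "case").iterdir())
        st.update(status="ok", intact_faces=len(case.intact_mesh.faces))
    except Exception as err:  # noqa: BLE001
        fail("phantom", err)

    # -- segmentation (rasterize the pre-op anatomy, regrow, re-surface) --
    st = stage("segmentation")
    preop_surface = case.preop_mesh
    try:
        if config.segmentation.enabled:
            sseed = case.preop_mesh.bounds.mean(axis=0)
            vol = rasterize(case.preop_mesh, config.segmentation.voxel_spacing_mm)
            ijk = tuple(
                int(round(v)) for v in (case.moving_preop.centroid - vol.origin) / vol.spacing
            )
            mask = seeded_segment(vol, [ijk], config.segmentation.threshold_hu)
            preop_surface = extract_surface(mask)
            st.update(
                status="ok",
                volume_shape=list(vol.data.shape),
                mask_voxels=mask.voxel_count,
                surface_faces=len(preop_surface.faces),
            )
        else:
            st.update(status="skipped")
    except Exception as err:  # noqa: BLE001
        fail("segmentation", err)

    # -- registration -----------------------------------------------------
    st = stage("registration")
    try:
        rc = config.registration
        plane, coarse, fine = recover_malunion_alignment(
            preop_surface,
            case.segment_outer_surface(),
            case.landmarks_preop,
            case.segment_landmark_names,
            displaced_side=rc.displaced_side,
            run_icp=rc.run_icp,
            icp_params=rc.icp.model_dump(),
            seed=stage_seed(config.seed, "registration"),
        )
        alignment = (fine or coarse).transform
        (fine or coarse).to_json(out / "registration.json", params=rc.model_dump())
        files.append(out / "registration.json")
        gt = case.ground_truth_malunion.inverse()
        st.update(
            status="ok",
            plane_residual_mm=plane.residual_rms_mm,
            rms_before_mm=coarse.rms_before_mm,
            rms_after_mm=(fine or coarse).rms_after_mm,
            iterations=(fine or coarse).iterations,
            rotation_error_deg=alignment.compose(gt.inverse()).rotation_angle_deg(),
            translation_error_mm=float(np.linalg.norm(alignment.translation - gt.translation)),
        )
    except Exception as err:  # noqa: BLE001
        fail("registration", err)

    # -- planning + verification -----------------------------------------
    st = stage("planning")
    try:
        pl = config.planning
        requests = default_hole_requests(
            case,
            alignment,
            n_moving=pl.n_moving_holes,
            n_stable=pl.n_stable_holes,
            diameter_mm=pl.hole_diameter_mm,
        )
        plan, _, _ = make_plan(
            case.preop_mesh,
            alignment,
            case.osteotomy_preop,
            requests,
            footprint_radius_mm=pl.footprint_radius_mm,
            guide_thickness_mm=pl.guide_thickness_mm,
            build_guide_meshes=pl.build_guides,
            precut=(case.moving_preop, case.stable),
        )
        plan.to_json(out / "plan.json", mesh_dir=out / "plan_meshes")
        files.append(out / "plan.json")
        if (out / "plan_meshes").exists():
            files += list((out / "plan_meshes").iterdir())
        verification = verify_plan(plan, tol_mm=1e-6)
        st.update(status="ok", verification=verification)
        if not verification["pass"]:
            raise RuntimeError("plan verification failed")
    except Exception as err:  # noqa: BLE001
        fail("planning", err)

    # -- simulated execution ----------------------------------------------
    st = stage("simulate")
    try:
        postop = simulate_execution(
            case,
            plan,
            exec_rot_sigma_deg=config.simulate.exec_rot_sigma_deg,
            exec_trans_sigma_mm=config.simulate.exec_trans_sigma_mm,
            seed=stage_seed(config.seed, "simulate"),
        )
        write_mesh(postop, out / "postop.stl")
        files.append(out / "postop.stl")
        st.update(status="ok")
    except Exception as err:  # noqa: BLE001
        fail("simulate", err)

    # -- evaluation --------------------------------------------------------
    st = stage("evaluation")
    try:
        ev = config.evaluation
        eseed = stage_seed(config.seed, "evaluation")
        planned_model = apply_transform(case.segment_outer_surface(), alignment)
        comparisons = {}
        # planned vs post-op (mesh path)
        _, s1 = compare_meshes(
            planned_model, postop, ev.samples_per_mm2, ev.bin_width_mm, seed=eseed
        )
        comparisons["planned_vs_postop"] = s1.to_dict()
        # pre-op vs post-op: how far the segment travelled
        preop_model = case.segment_outer_surface()
        _, s2 = compare_meshes(
            preop_model, postop, ev.samples_per_mm2, ev.bin_width_mm, seed=eseed + 1
        )
        comparisons["preop_vs_postop"] = s2.to_dict()
        # voxel-path comparison against a re-segmented post-op scan
        if config.segmentation.enabled:
            vol = rasterize(postop, config.segmentation.voxel_spacing_mm)
            ijk = tuple(
                int(round(v))
                for v in (alignment.apply(case.moving_preop.centroid) - vol.origin) / vol.spacing
            )
            mask = seeded_segment(vol, [ijk], config.segmentation.threshold_hu)
            recon = extract_surface(mask)
            _, s3 = compare_meshes(
                planned_model, recon, ev.samples_per_mm2, ev.bin_width_mm, seed=eseed + 2
            )
            comparisons["planned_vs_postop_ct"] = s3.to_dict()
        if ev.write_heatmaps:
            write_heatmap(planned_model, postop, out / "heatmap_planned_vs_postop.ply")
            files.append(out / "heatmap_planned_vs_postop.ply")
        # single-landmark three-axis displacement (infraorbital-rim analog)
        from zygoplan.evaluation import landmark_displacement

        lm_pre = case.landmarks_preop.get("zygoma_apex", config.registration.displaced_side)
        lm_post = alignment.apply(lm_pre)
        comparisons["apex_displacement"] = landmark_displacement(lm_pre, lm_post)
        st.update(status="ok", comparisons=comparisons)
    except Exception as err:  # noqa: BLE001
        fail("evaluation", err)

    report["summary"] = {
        "verify_pass": report["stages"]["planning"]["verification"]["pass"],
        "planned_vs_postop_mean_mm": comparisons["planned_vs_postop"]["mean_abs_mm"],
        "preop_vs_postop_mean_mm": comparisons["preop_vs_postop"]["mean_abs_mm"],
    }
    _write_report(report, out, files)
    return report


def _write_report(report: dict, out: Path, files: list[Path]) -> None:
    for f in files:
        if Path(f).exists():
            report["manifest"][str(Path(f).relative_to(out))] = _sha256(Path(f))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
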