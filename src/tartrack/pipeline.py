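"""End-to-end pipeline: phantom (or supplied) inputs → hybrid models →
dynamic tracking → distance verification → joint kinematics.

Every run writes a self-contained run directory: hybrid model bundles,
tracking CSVs with per-frame costs and flags, a distance-verification
report (JSON), stance-normalized kinematics (CSV), a review report and a
manifest recording the resolved configuration and seed.  In phantom mode
the ground truth is also written so recovery errors can be audited.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .distance import (signed_distance, trial_summary,
                       PENETRATION_LIMIT_MM, GAP_LIMIT_MM)
from .drr import (DRRVolume, hollow_implant, isolate_bone,
                  mesh_to_binary_stack, rasterize_occupancy)
from .frames import build_talus_frame, build_tibia_frame
from .geometry import (Pose, RigidTransform, compose, invert,
                       rotation_angle_deg, poses_to_csv)
from .hybrid import (HybridModel, assemble_hybrid_drr, fill_interface,
                     link_implant_to_bone, register_static)
from .kinematics import (butterworth_lowpass, detect_gait_events,
                         joint_angle_series, normalize_to_stance,
                         residual_cutoff, DEFAULT_CUTOFF_HZ, STANCE_SAMPLES)
from .phantom import (PhantomConfig, build_phantom, render_fluoro_sequence,
                      synthesize_gait_trajectory)
from .projection import default_biplane_rig
from .tracking import CompoundDRR, register_static_multi, track_sequence_multi
from .volume import Grid

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


class ConfigError(ValueError):
    """Raised for invalid or unknown pipeline configuration keys."""


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults are desk-scale (coarse phantom, reduced frame rate and image
    size) so a full run completes in minutes on one CPU; the full-scale
    acquisition of the method (0.6 mm CT, 200 Hz, 608×600 images) is a
    matter of raising these numbers.
    """

    seed: int = 0
    output_dir: str = "runs/phantom"
    side: str = "left"
    phantom_mode: bool = True
    # phantom scale
    phantom_spacing_mm: float = 1.2
    phantom_arc_points: int = 17
    phantom_mesh_layers: int = 7
    phantom_tube_sections: int = 24
    phantom_clearance_mm: float = 1.0
    phantom_artifact_strength: float = 1.0
    phantom_pad_frames: int = 1
    n_stance_frames: int = 20
    frame_rate_hz: float = 28.6     # 20 frames over the 0.7 s stance
    n_static_frames: int = 2
    # imaging
    image_resolution: int = 160
    fov_mm: float = 120.0
    poisson_noise: bool = False
    # tracker
    tracker_max_evals: int = 120
    tracker_polish_evals: int = 80
    tracker_restarts: int = 0
    review_threshold: float = 0.7
    init_translation_offset_mm: float = 1.5
    init_rotation_offset_deg: float = 1.5
    # interface fill
    max_gap_mm: float = 3.0
    # filter
    filter_cutoff_hz: float = DEFAULT_CUTOFF_HZ
    filter_auto_cutoff: bool = False
    filter_order_interpretation: str = "effective"
    # acceptance band
    penetration_limit_mm: float = PENETRATION_LIMIT_MM
    gap_limit_mm: float = GAP_LIMIT_MM

    def __post_init__(self):
        if self.side not in ("left", "right"):
            raise ConfigError("side must be 'left' or 'right'")
        if self.penetration_limit_mm >= self.gap_limit_mm:
            raise ConfigError("acceptance band is empty")
        if self.filter_order_interpretation not in ("effective", "per_pass"):
            raise ConfigError("filter order interpretation must be "
                              "'effective' or 'per_pass'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Pointers to run artifacts plus the headline numbers."""

    run_dir: Path
    verification: dict
    kinematics_csv: Path
    tracking_errors: dict
    angle_rms_deg: dict
    link_errors: dict

    @property
    def verification_passed(self) -> bool:
        return bool(self.verification.get("trial_pass", False))


def _perturbed_init(truth: Pose, rng: np.random.Generator,
                    d_mm: float, d_deg: float) -> Pose:
    from .tracking import _rotvec_matrix
    dR = _rotvec_matrix(rng.uniform(-d_deg, d_deg, 3) / np.sqrt(3))
    dt = rng.uniform(-d_mm, d_mm, 3) / np.sqrt(3)
    return Pose(RigidTransform(dR @ truth.rotation, truth.translation + dt,
                               truth.transform.source_space,
                               truth.transform.target_space),
                truth.frame_index, truth.frame_rate_hz)


def _cad_grid(mesh, spacing_mm: float, margin_mm: float = 3.0,
              refine: float = 0.5) -> Grid:
    """Grid around an implant CAD mesh.  CAD geometry is exact, so implant
    DRRs default to half the CT voxel size (``refine=0.5``)."""
    spacing_mm = refine * spacing_mm
    lo = mesh.bounds[0] - margin_mm
    hi = mesh.bounds[1] + margin_mm
    shape = np.maximum(np.ceil((hi - lo) / spacing_mm).astype(int) + 1, 2)
    return Grid(tuple(shape), [spacing_mm] * 3, lo)


def _pose_errors(tracked, truth) -> dict:
    dt = [np.linalg.norm(a.translation - b.translation)
          for a, b in zip(tracked, truth)]
    dr = [rotation_angle_deg(a.rotation.T @ b.rotation)
          for a, b in zip(tracked, truth)]
    return {"rms_translation_mm": float(np.sqrt(np.mean(np.square(dt)))),
            "rms_rotation_deg": float(np.sqrt(np.mean(np.square(dr)))),
            "max_translation_mm": float(np.max(dt)),
            "max_rotation_deg": float(np.max(dr))}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full workflow and populate the run directory.

    Phantom mode generates the scene, static and walking trials itself;
    all downstream stages (static registration, linking, re-segmentation,
    hybrid DRR assembly, dynamic tracking, distance verification,
    kinematics) then run exactly as they would on acquired data.
    """
    if not config.phantom_mode:
        raise NotImplementedError(
            "only phantom mode is wired end-to-end; use the library stages "
            "directly for externally supplied data")
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    run_dir = Path(cfg.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    # ---- stage: phantom -------------------------------------------------
    pcfg = PhantomConfig(
        spacing_mm=cfg.phantom_spacing_mm, arc_points=cfg.phantom_arc_points,
        mesh_layers=cfg.phantom_mesh_layers,
        tube_sections=cfg.phantom_tube_sections,
        clearance_mm=cfg.phantom_clearance_mm,
        artifact_strength=cfg.phantom_artifact_strength,
        n_pad_frames=cfg.phantom_pad_frames,
        frame_rate_hz=cfg.frame_rate_hz, side=cfg.side)
    scene, volume = build_phantom(pcfg, seed=cfg.seed)
    traj = synthesize_gait_trajectory(scene, seed=cfg.seed,
                                      n_stance_frames=cfg.n_stance_frames,
                                      frame_rate_hz=cfg.frame_rate_hz)
    scene_center = (scene.grid.origin
                    + 0.5 * np.array(scene.grid.shape) * scene.grid.spacing)
    cameras = default_biplane_rig(scene_center,
                                  resolution=cfg.image_resolution,
                                  fov_mm=cfg.fov_mm)
    stacks = render_fluoro_sequence(scene, traj, cameras,
                                    poisson_noise=cfg.poisson_noise,
                                    seed=cfg.seed)
    for i, stack in enumerate(stacks):
        tifffile.imwrite(run_dir / f"fluoro_cam{i + 1}.tiff", stack)
    (run_dir / "calibration.json").write_text(json.dumps(
        [c.to_dict() for c in cameras], indent=2))
    pd.DataFrame({"time_s": traj.time_s, "fz_N": traj.force_n}).to_csv(
        run_dir / "force.csv", index=False)

    # ---- stage: individual DRRs ----------------------------------------
    bone_drrs = {
        "tibia": isolate_bone(volume, scene.tibia_mask_initial),
        "talus": isolate_bone(volume, scene.talus_mask_initial),
    }
    implants = {
        "tray": (scene.tray_mesh, scene.tray_to_tibia, "tibia"),
        "dome": (scene.dome_mesh, scene.dome_to_talus, "talus"),
    }
    # metal reads at the very top of the CT histogram; that sets the solid
    # implant DRR intensity used for static matching and subtraction
    implant_intensity = float(np.quantile(volume.intensities, 0.999))
    implant_drrs = {}
    implant_solid_drrs = {}
    for name, (mesh, _true_link, _bone) in implants.items():
        # hollowed stack at the CT spacing: its one-voxel edge shell must
        # survive nearest-neighbor resampling onto the CT grid at assembly
        grid_ct = _cad_grid(mesh, cfg.phantom_spacing_mm, refine=1.0)
        mask_ct = mesh_to_binary_stack(mesh, grid_ct)
        implant_drrs[name] = DRRVolume(
            hollow_implant(mask_ct).astype(np.float32), grid_ct, "implant")
        # solid DRR for matching/subtraction: antialiased occupancy at
        # sub-CT resolution, so the silhouette carries no grid-phase bias
        grid = _cad_grid(mesh, cfg.phantom_spacing_mm)
        implant_solid_drrs[name] = DRRVolume(
            rasterize_occupancy(mesh, grid) * implant_intensity, grid,
            "implant")

    # ---- stage: static trial + registration -----------------------------
    static_truth = scene.static_poses()
    static_traj = _constant_trajectory(traj, static_truth, cfg.n_static_frames)
    static_stacks = render_fluoro_sequence(scene, static_traj, cameras,
                                           poisson_noise=cfg.poisson_noise,
                                           seed=cfg.seed + 1)
    static_frames = [(static_stacks[0][i], static_stacks[1][i])
                     for i in range(cfg.n_static_frames)]

    object_truth = {
        "tibia": static_truth["tibia"],
        "talus": static_truth["talus"],
        "tray": _implant_world_pose(static_truth["tibia"], scene.tray_to_tibia),
        "dome": _implant_world_pose(static_truth["talus"], scene.dome_to_talus),
    }
    # bones are matched with the implant's neighborhood excluded from
    # their attention window: the initial segmentation is unreliable next
    # to metal, so the bone pose must come from clean edges
    static_objects = {
        "tibia": {"drr": bone_drrs["tibia"], "render": bone_drrs["tibia"],
                  "exclude": ["tray", "dome"]},
        "talus": {"drr": bone_drrs["talus"], "render": bone_drrs["talus"],
                  "exclude": ["tray", "dome"]},
        "tray": {"drr": implant_solid_drrs["tray"],
                 "render": implant_solid_drrs["tray"]},
        "dome": {"drr": implant_solid_drrs["dome"],
                 "render": implant_solid_drrs["dome"]},
    }
    inits = {name: _perturbed_init(truth, rng, cfg.init_translation_offset_mm,
                                   cfg.init_rotation_offset_deg)
             for name, truth in object_truth.items()}
    mean_static = register_static_multi(
        static_objects, static_frames, cameras, inits, seed=cfg.seed,
        sweeps=2, max_evals=cfg.tracker_max_evals,
        polish_evals=cfg.tracker_polish_evals,
        n_restarts=cfg.tracker_restarts,
        review_threshold=cfg.review_threshold)
    links = {
        "tray": link_implant_to_bone(mean_static["tibia"], mean_static["tray"]),
        "dome": link_implant_to_bone(mean_static["talus"], mean_static["dome"]),
    }

    # ---- stage: re-segmentation ------------------------------------------
    filled_masks, filled_drrs = _resegment_bones(scene, volume, links,
                                                 implants, cfg)
    link_errors = {}
    for name, (_mesh, true_link, _bone) in implants.items():
        est = links[name]
        link_errors[name] = {
            "translation_mm": float(np.linalg.norm(
                est.translation - true_link.translation)),
            "rotation_deg": rotation_angle_deg(
                est.rotation.T @ true_link.rotation),
        }

    hybrids = {}
    for bone, implant_name in (("tibia", "tray"), ("talus", "dome")):
        mesh, _t, _b = implants[implant_name]
        placed = mesh.copy()
        placed.apply_transform(links[implant_name].matrix)
        implant_mask_ct = mesh_to_binary_stack(placed, scene.grid)
        hybrid_drr = assemble_hybrid_drr(filled_drrs[bone],
                                         implant_drrs[implant_name],
                                         links[implant_name])
        bone_mesh = scene.tibia_mesh if bone == "tibia" else scene.talus_mesh
        hollow_ct = hollow_implant(implant_mask_ct)
        model = HybridModel(bone_mesh, filled_masks[bone], mesh,
                            hollow_ct.astype(bool), links[implant_name],
                            hybrid_drr, cfg.side)
        model.save(run_dir / f"hybrid_{bone}")
        hybrids[bone] = model

    # ---- stage: dynamic tracking ----------------------------------------
    # subtraction render model per body: bone at CT intensity plus the
    # linked solid implant (fine CAD grid resampled onto the CT grid)
    dyn_objects = {}
    for body, implant_name in (("talus", "dome"), ("tibia", "tray")):
        render = CompoundDRR([
            (filled_drrs[body], None),
            (implant_solid_drrs[implant_name], links[implant_name]),
        ])
        dyn_objects[body] = {"drr": render, "render": render}
    truth_poses = {"tibia": traj.tibia_poses, "talus": traj.talus_poses}
    dyn_inits = {
        body: _perturbed_init(truth_poses[body][0], rng,
                              cfg.init_translation_offset_mm,
                              cfg.init_rotation_offset_deg)
        for body in dyn_objects}
    results = track_sequence_multi(dyn_objects, stacks, cameras, dyn_inits,
                                   seed=cfg.seed + 100, sweeps=2,
                                   max_evals=cfg.tracker_max_evals,
                                   polish_evals=cfg.tracker_polish_evals,
                                   n_restarts=cfg.tracker_restarts,
                                   review_threshold=cfg.review_threshold)
    tracking_errors = {}
    tracked = {}
    for body, result in results.items():
        result.to_csv(run_dir / f"tracking_{body}.csv")
        (run_dir / f"review_{body}.json").write_text(
            json.dumps(result.review_report(), indent=2))
        tracked[body] = result
        tracking_errors[body] = _pose_errors(result.poses, truth_poses[body])

    # ---- stage: distance verification ------------------------------------
    insert_to_tray = compose(invert(scene.tray_to_tibia), scene.insert_to_tibia)
    polymer_link = compose(links["tray"], insert_to_tray)
    patch_cad = scene.insert_mesh.vertices[scene.insert_articular_patch()]
    dome_mesh_talus = scene.dome_mesh.copy()
    dome_mesh_talus.apply_transform(links["dome"].matrix)
    maps = []
    for i in range(traj.n_frames):
        patch_world = compose(tracked["tibia"].poses[i].transform,
                              polymer_link).apply(patch_cad)
        dome_world = dome_mesh_talus.copy()
        dome_world.apply_transform(tracked["talus"].poses[i].transform.matrix)
        maps.append(signed_distance(patch_world, dome_world, frame_index=i))
    verification = trial_summary(maps, cfg.penetration_limit_mm,
                                 cfg.gap_limit_mm)
    (run_dir / "distance_report.json").write_text(
        json.dumps(verification, indent=2))
    from .distance import maps_to_csv, save_distance_ply
    maps_to_csv(maps, run_dir / "distance_summary.csv")
    hs_patch = compose(tracked["tibia"].poses[0].transform,
                       polymer_link).apply(patch_cad)
    save_distance_ply(hs_patch, maps[0], run_dir / "distance_heel_strike.ply")

    # ---- stage: anatomical frames + kinematics ---------------------------
    tibia_sel = _tibia_selections_from_links(scene, polymer_link,
                                             links["tray"])
    talus_sel = _talus_selections_from_links(scene, links["dome"])
    tibia_frame = build_tibia_frame(tibia_sel, cfg.side)
    talus_frame = build_talus_frame(talus_sel, cfg.side)

    angles = joint_angle_series(tracked["tibia"].poses,
                                tracked["talus"].poses,
                                tibia_frame, talus_frame, cfg.side)
    if cfg.filter_auto_cutoff:
        cutoff = residual_cutoff(angles.dorsiflexion, cfg.frame_rate_hz,
                                 order_interpretation=cfg.filter_order_interpretation)
    else:
        cutoff = cfg.filter_cutoff_hz
    filtered = {k: butterworth_lowpass(v, cfg.frame_rate_hz, cutoff,
                                       cfg.filter_order_interpretation)
                for k, v in angles.as_dict().items()}
    events = detect_gait_events(traj.force_n, cfg.frame_rate_hz)
    normalized = normalize_to_stance(filtered, events)
    percent = np.linspace(0.0, 100.0, STANCE_SAMPLES)
    kin = pd.DataFrame({
        "percent_stance": percent,
        "dorsiflexion_deg": normalized["dorsiflexion"],
        "inversion_deg": normalized["inversion"],
        "internal_rotation_deg": normalized["internal_rotation"],
    })
    raw_norm = normalize_to_stance(angles.as_dict(), events)
    for k in raw_norm:
        kin[f"{k}_unfiltered_deg"] = raw_norm[k]
    kin_path = run_dir / "kinematics.csv"
    kin.to_csv(kin_path, index=False)

    true_norm = normalize_to_stance(traj.true_angles_deg, events)
    angle_rms = {
        k: float(np.sqrt(np.mean((normalized[k] - true_norm[k]) ** 2)))
        for k in normalized}
    pd.DataFrame({"percent_stance": percent, **{
        f"{k}_deg": v for k, v in true_norm.items()}}).to_csv(
        run_dir / "ground_truth_kinematics.csv", index=False)
    poses_to_csv(traj.tibia_poses, run_dir / "ground_truth_tibia_poses.csv")
    poses_to_csv(traj.talus_poses, run_dir / "ground_truth_talus_poses.csv")

    manifest = {
        "tartrack_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "filter_cutoff_hz": float(cutoff),
        "gait_events": {"heel_strike": events.heel_strike,
                        "toe_off": events.toe_off,
                        "threshold_n": events.threshold_n},
        "link_errors": link_errors,
        "tracking_errors": tracking_errors,
        "angle_rms_deg": angle_rms,
        "verification_pass": bool(verification["trial_pass"]),
        "trial_mean_distance_mm": verification["trial_mean_mm"],
    }
    (run_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    return PipelineResult(run_dir, verification, kin_path, tracking_errors,
                          angle_rms, link_errors)


def _unconditioned_hybrid(bone_drr: DRRVolume, implant_solid: DRRVolume,
                          link: RigidTransform) -> DRRVolume:
    """Render model for residual subtraction: bone CT intensities merged
    with the linked solid implant, no display conditioning."""
    from .hybrid import assemble_hybrid_drr
    return assemble_hybrid_drr(bone_drr, implant_solid, link, condition=False)


def _resegment_bones(scene, volume, links: dict, implants: dict,
                     cfg: PipelineConfig) -> tuple[dict, dict]:
    """Interface re-segmentation for both bones under the current links.

    Returns ``(filled_masks, filled_bone_drrs)``; voxels added by the fill
    read as bone material rather than the low CT value the artifact left.
    """
    filled_masks, filled_drrs = {}, {}
    for bone, implant_name in (("tibia", "tray"), ("talus", "dome")):
        mesh, _true_link, _b = implants[implant_name]
        placed = mesh.copy()
        placed.apply_transform(links[implant_name].matrix)
        implant_mask_ct = mesh_to_binary_stack(placed, scene.grid)
        bone_mask = (scene.tibia_mask_initial if bone == "tibia"
                     else scene.talus_mask_initial)
        filled = fill_interface(bone_mask, implant_mask_ct,
                                scene.grid.spacing, cfg.max_gap_mm)
        bone_drr = isolate_bone(volume, filled)
        added = filled & ~bone_mask
        fill_value = float(np.mean(volume.intensities[bone_mask])) \
            if bone_mask.any() else 0.0
        bone_drr.intensities[added] = np.maximum(
            bone_drr.intensities[added], fill_value)
        filled_masks[bone] = filled
        filled_drrs[bone] = bone_drr
    return filled_masks, filled_drrs


def _implant_world_pose(bone_pose: Pose, implant_to_bone: RigidTransform) -> Pose:
    return Pose(compose(bone_pose.transform, implant_to_bone),
                bone_pose.frame_index, bone_pose.frame_rate_hz)


def _constant_trajectory(template, static_truth: dict, n_frames: int):
    """A short static trial: the standing poses repeated per frame."""
    from .phantom import GroundTruthTrajectory
    tib = [Pose(static_truth["tibia"].transform, i,
                static_truth["tibia"].frame_rate_hz) for i in range(n_frames)]
    tal = [Pose(static_truth["talus"].transform, i,
                static_truth["talus"].frame_rate_hz) for i in range(n_frames)]
    fs = static_truth["tibia"].frame_rate_hz
    return GroundTruthTrajectory(
        tib, tal, np.zeros(n_frames), np.arange(n_frames) / fs,
        {k: np.zeros(n_frames) for k in template.true_angles_deg},
        0, n_frames - 1, template.tibia_frame_basis,
        template.talus_frame_basis, fs)


def _tibia_selections_from_links(scene, polymer_link: RigidTransform,
                                 tray_link: RigidTransform) -> dict:
    cfg = scene.config
    ins = scene.insert_mesh.vertices
    r = np.hypot(ins[:, 1], ins[:, 2])
    arc = ins[np.abs(r - (cfg.dome_radius + cfg.clearance_mm)) < 1e-6]
    tib = scene.tibia_mesh.vertices
    rho = np.hypot(tib[:, 0], tib[:, 1])
    shaft = tib[(np.abs(rho - cfg.tibia_outer_radius) < 1e-6)
                & (tib[:, 2] > cfg.tibia_base_z + 0.5 * cfg.tibia_length)]
    medial_sign = -1.0 if cfg.side == "left" else 1.0
    medial_edge_cad = np.array([medial_sign * cfg.tray_half_width, 0.0,
                                -cfg.tray_thickness])
    base_cad = np.array([0.0, 0.0, -cfg.tray_thickness])
    return {
        "articular_patch": polymer_link.apply(arc),
        "shaft_patch": shaft,
        "medial_edge_point": tray_link.apply(medial_edge_cad),
        "implant_base_point": tray_link.apply(base_cad),
    }


def _talus_selections_from_links(scene, dome_link: RigidTransform) -> dict:
    sel = scene.talus_frame_selections()
    pts_cad = scene.dome_articular_patch_points(space="cad")
    sel["dome_patch"] = dome_link.apply(pts_cad)
    return sel
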