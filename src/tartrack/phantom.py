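"""Synthetic ankle-replacement phantom with known ground truth.

Generates everything the tracking workflow consumes, so every downstream
stage is testable without patient data:

* a CT-like intensity volume of a left ankle after total ankle replacement
  (cortical shell / trabecular interior / soft tissue / metal), with an
  optional simulated metal-artifact corruption band around the implants —
  the problem the hybrid-model method works around;
* watertight parametric implant stand-ins (tibial tray with keel, fixed-
  bearing polymer insert with a cylindrically concave inferior face, and a
  bicondylar cylindrically convex talar dome) with known rigid
  implant-to-bone placements;
* a stance-phase gait trajectory for tibia and talus at the fluoroscopy
  frame rate, built by composing joint-coordinate-system rotations about
  the dome axis, together with a synchronized double-hump vertical
  ground-reaction-force trace;
* biplane perspective projection sequences rendered with the same ray
  caster the tracker uses.

Coordinates (CT space, mm, left limb): +x subject's left (lateral),
medial = −x; +y anterior; +z superior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .drr import mesh_to_binary_stack
from .geometry import Pose, RigidTransform
from .meshes import (concave_slab_profile, cylinder_segment_profile,
                     extrude_profile, tube_mesh)
from .projection import CameraModel, project_volume
from .volume import CTVolume, Grid

__all__ = ["PhantomConfig", "PhantomScene", "GroundTruthTrajectory",
           "build_implant_meshes",
           "PhantomConfigError", "build_phantom", "simulate_metal_artifact",
           "synthesize_gait_trajectory", "render_fluoro_sequence"]


class PhantomConfigError(ValueError):
    """Raised for geometrically impossible phantom configurations."""


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and acquisition parameters of the phantom.

    Dimensions are millimetres, typical of a trabecular-metal total ankle
    replacement; intensities are HU-like arbitrary units.
    """

    # volume
    spacing_mm: float = 0.6
    margin_mm: float = 6.0
    # tibia (cortical tube)
    tibia_outer_radius: float = 15.0
    tibia_inner_radius: float = 7.5
    tibia_length: float = 42.0
    # tibial tray (plate + keel)
    tray_half_width: float = 14.0     # ML
    tray_half_depth: float = 13.0     # AP
    tray_thickness: float = 4.0
    keel_half_width: float = 2.0
    keel_half_depth: float = 5.0
    keel_height: float = 8.0
    # polymer insert
    insert_half_width: float = 13.0   # ML
    insert_half_depth: float = 13.0   # AP
    insert_top_above_axis: float = 24.0
    # talar dome (bicondylar cylinder segments about an ML axis)
    dome_radius: float = 20.0
    dome_half_width: float = 14.0
    groove_half_width: float = 3.0
    groove_depth: float = 0.6
    clearance_mm: float = 1.0         # designed radial articular clearance
    # medial malleolus stand-in (distal process beside the joint line;
    # also what makes tibial axial rotation observable on projections)
    malleolus_width: float = 6.0
    malleolus_half_depth: float = 6.0
    malleolus_height: float = 14.0
    # anterior crest: shallow fin along the shaft (the tibia is triangular,
    # not cylindrical; the crest pins axial rotation in projections)
    crest_height: float = 4.0
    crest_half_width: float = 3.0
    # talus block
    talus_half_width: float = 16.0
    talus_half_depth: float = 17.0
    talus_height: float = 14.0
    # width of the under-segmented band next to the implants: metal
    # artifact prevents outlining cortical bone there, so the *initial*
    # segmentation masks stop short of the implant by this much; the
    # re-segmentation stage must close the gap.  The physical bone is
    # continuous up to the implant (separated by a hair so the solids stay
    # disjoint).
    segmentation_gap_mm: float = 1.8
    physical_gap_mm: float = 0.05
    # intensities (HU-like)
    soft_tissue_intensity: float = 100.0
    trabecular_intensity: float = 400.0
    cortical_intensity: float = 1200.0
    implant_intensity: float = 3000.0
    cortical_thickness: float = 2.4
    # artifact
    artifact_strength: float = 1.0
    artifact_band_mm: float = 6.0
    # mesh tessellation
    arc_points: int = 33
    mesh_layers: int = 9
    tube_sections: int = 48
    include_implants: bool = True
    side: str = "left"
    # gait / acquisition
    frame_rate_hz: float = 200.0
    stance_duration_s: float = 0.7
    n_pad_frames: int = 6
    peak_force_n: float = 750.0
    angle_noise_deg: float = 0.15

    # -- derived geometry ---------------------------------------------------

    @property
    def dome_axis_z(self) -> float:
        """z of the dome cylinder axis in CT space."""
        return self.talus_height + self.physical_gap_mm + 8.0 - self.dome_radius

    @property
    def dome_apex_z(self) -> float:
        return self.dome_axis_z + self.dome_radius

    @property
    def dome_chord_z(self) -> float:
        return self.talus_height + self.physical_gap_mm

    @property
    def tray_bottom_z(self) -> float:
        return self.insert_top_above_axis + self.dome_axis_z

    @property
    def tray_top_z(self) -> float:
        return self.tray_bottom_z + self.tray_thickness

    @property
    def tibia_base_z(self) -> float:
        return self.tray_top_z + self.physical_gap_mm

    def validate(self) -> None:
        if self.tray_half_width > self.tibia_outer_radius:
            raise PhantomConfigError("tibial tray wider than the tibia envelope")
        if self.dome_half_width > self.talus_half_width:
            raise PhantomConfigError("talar dome wider than the talus envelope")
        if np.hypot(self.keel_half_width, self.keel_half_depth) >= self.tibia_inner_radius:
            raise PhantomConfigError("keel does not fit in the medullary canal")
        if self.clearance_mm < 0:
            raise PhantomConfigError("articular clearance must be non-negative")
        if self.spacing_mm <= 0 or self.stance_duration_s <= 0:
            raise PhantomConfigError("spacing and stance duration must be positive")


@dataclass
class GroundTruthTrajectory:
    """Per-frame ground-truth poses, force trace and true joint angles."""

    tibia_poses: list
    talus_poses: list
    force_n: np.ndarray
    time_s: np.ndarray
    true_angles_deg: dict          # dorsiflexion / inversion / internal_rotation
    stance_start: int              # first frame of stance (ground truth)
    stance_end: int                # last frame of stance (inclusive)
    tibia_frame_basis: np.ndarray  # anatomical bases used to compose rotations
    talus_frame_basis: np.ndarray
    frame_rate_hz: float

    @property
    def n_frames(self) -> int:
        return len(self.tibia_poses)


@dataclass
class PhantomScene:
    """All phantom geometry, masks, placements and the CT volume."""

    config: PhantomConfig
    seed: int
    volume: CTVolume
    clean_volume: CTVolume          # before metal-artifact corruption
    tibia_mesh: trimesh.Trimesh     # CT space
    talus_mesh: trimesh.Trimesh
    tray_mesh: trimesh.Trimesh      # CAD space
    insert_mesh: trimesh.Trimesh
    dome_mesh: trimesh.Trimesh
    tray_to_tibia: RigidTransform   # CAD -> CT ground-truth placements
    insert_to_tibia: RigidTransform
    dome_to_talus: RigidTransform
    tibia_mask: np.ndarray          # true (continuous to the implant)
    talus_mask: np.ndarray
    tray_mask: np.ndarray
    dome_mask: np.ndarray
    tibia_mask_initial: np.ndarray  # what artifact-limited segmentation yields
    talus_mask_initial: np.ndarray

    @property
    def grid(self) -> Grid:
        return self.volume.grid

    # -- rendering volumes --------------------------------------------------

    def rigid_body_volume(self, body: str) -> CTVolume:
        """Clean intensity volume of one rigid complex (bone + its implant),
        rasterized on the CT grid."""
        if body == "tibia":
            mask = self.tibia_mask | self.tray_mask
        elif body == "talus":
            mask = self.talus_mask | self.dome_mask
        else:
            raise ValueError(f"unknown rigid body {body!r}")
        vol = self.clean_volume.copy()
        vol.intensities = vol.intensities * mask
        return vol

    def bone_volume(self, body: str) -> CTVolume:
        """Clean intensity volume of one bone alone (no implant)."""
        mask = self.tibia_mask if body == "tibia" else self.talus_mask
        vol = self.clean_volume.copy()
        vol.intensities = vol.intensities * mask
        return vol

    def implant_solid_volume(self, name: str, refine: float = 0.5) -> CTVolume:
        """Uniform-intensity solid volume of one implant in its CAD space.

        Implants are exact CAD solids, so they are rasterized on their own
        grid at ``refine`` × the CT voxel size — the rendered silhouette
        then carries sub-CT-voxel boundary fidelity, as a physical metal
        part does on fluoroscopy.
        """
        key = (name, refine)
        cache = getattr(self, "_implant_volume_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_implant_volume_cache", cache)
        if key not in cache:
            from .drr import rasterize_occupancy
            mesh = {"tray": self.tray_mesh, "dome": self.dome_mesh}[name]
            spacing = refine * self.config.spacing_mm
            lo = mesh.bounds[0] - 2.0
            hi = mesh.bounds[1] + 2.0
            shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2)
            grid = Grid(tuple(shape), [spacing] * 3, lo)
            occ = rasterize_occupancy(mesh, grid)
            cache[key] = CTVolume(occ * self.config.implant_intensity,
                                  grid.spacing, grid.origin)
        return cache[key]

    # -- articular patch / landmark selections (CAD or CT coordinates) -----

    def insert_articular_patch(self) -> np.ndarray:
        """Indices of insert-CAD vertices on the concave articular face that
        lie over the dome condyles (the faces "selected" for distance maps)."""
        cfg = self.config
        v = self.insert_mesh.vertices
        r = np.hypot(v[:, 1], v[:, 2])  # arc center at CAD origin
        on_arc = np.abs(r - (cfg.dome_radius + cfg.clearance_mm)) < 1e-6
        over_condyle = (np.abs(v[:, 0]) > cfg.groove_half_width + 0.5) & \
                       (np.abs(v[:, 0]) < cfg.dome_half_width - 0.5)
        return np.nonzero(on_arc & over_condyle)[0]

    def dome_articular_patch_points(self, space: str = "ct") -> np.ndarray:
        """Points on the dome condyle surfaces (cylinder radius R)."""
        cfg = self.config
        v = self.dome_mesh.vertices
        r = np.hypot(v[:, 1], v[:, 2])
        on_cyl = (np.abs(r - cfg.dome_radius) < 1e-6) & \
                 (np.abs(v[:, 0]) > cfg.groove_half_width + 1e-9)
        pts = v[on_cyl]
        return self.dome_to_talus.apply(pts) if space == "ct" else pts

    def tibia_frame_selections(self) -> dict:
        """Landmarks for the tibial anatomical frame, CT coordinates."""
        cfg = self.config
        ins = self.insert_mesh.vertices
        r = np.hypot(ins[:, 1], ins[:, 2])
        arc = ins[np.abs(r - (cfg.dome_radius + cfg.clearance_mm)) < 1e-6]
        tib = self.tibia_mesh.vertices
        rho = np.hypot(tib[:, 0], tib[:, 1])
        shaft = tib[(np.abs(rho - cfg.tibia_outer_radius) < 1e-6)
                    & (tib[:, 2] > cfg.tibia_base_z + 0.5 * cfg.tibia_length)]
        medial_sign = -1.0 if cfg.side == "left" else 1.0
        medial_edge = np.array([medial_sign * cfg.tray_half_width, 0.0,
                                cfg.tray_bottom_z])
        return {
            "articular_patch": self.insert_to_tibia.apply(arc),
            "shaft_patch": shaft,
            "medial_edge_point": medial_edge,
            "implant_base_plane_z": cfg.tray_bottom_z,
        }

    def talus_frame_selections(self) -> dict:
        cfg = self.config
        tal = self.talus_mesh.vertices
        top = np.abs(tal[:, 2] - cfg.talus_height) < 1e-6
        ant = tal[top & (np.abs(tal[:, 1] - cfg.talus_half_depth) < 1e-6)]
        post = tal[top & (np.abs(tal[:, 1] + cfg.talus_half_depth) < 1e-6)]
        return {
            "dome_patch": self.dome_articular_patch_points("ct"),
            "anterior_spline": ant[np.argsort(ant[:, 0])],
            "posterior_spline": post[np.argsort(post[:, 0])],
        }

    def analytic_frame_bases(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact anatomical bases (columns ML, AP, SI) for both bones."""
        medial = -1.0 if self.config.side == "left" else 1.0
        basis = np.array([[medial, 0.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]]).T  # columns ML, AP, SI
        return basis.copy(), basis.copy()

    def static_poses(self, seed: int | None = None) -> dict:
        """Ground-truth standing poses for the static trial (model -> world)."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        poses = {}
        for body in ("tibia", "talus"):
            ang = np.radians(rng.uniform(-2, 2, size=3))
            t = rng.uniform(-3, 3, size=3)
            poses[body] = Pose(RigidTransform(_rot_xyz(ang), t, "ct", "mbt"),
                               frame_index=0,
                               frame_rate_hz=self.config.frame_rate_hz)
        return poses


def _rot_axis(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * K @ K


def _rot_xyz(angles_rad) -> np.ndarray:
    ax, ay, az = angles_rad
    return (_rot_axis([1, 0, 0], ax) @ _rot_axis([0, 1, 0], ay)
            @ _rot_axis([0, 0, 1], az))


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def build_implant_meshes(cfg: PhantomConfig):
    """Implant stand-ins in their CAD spaces.

    Tray CAD origin: center of the plate top face.  Insert and dome CAD
    origin: on the articulation cylinder axis (ML-directed through 0)."""
    # Tray: plate profile in (x, z) extruded along y, keel likewise.
    plate = extrude_profile(
        np.array([[-cfg.tray_half_width, -cfg.tray_thickness],
                  [cfg.tray_half_width, -cfg.tray_thickness],
                  [cfg.tray_half_width, 0.0],
                  [-cfg.tray_half_width, 0.0]]),
        -cfg.tray_half_depth, cfg.tray_half_depth, axis="y",
        n_layers=cfg.mesh_layers)
    keel = extrude_profile(
        np.array([[-cfg.keel_half_width, 0.0],
                  [cfg.keel_half_width, 0.0],
                  [cfg.keel_half_width, cfg.keel_height],
                  [-cfg.keel_half_width, cfg.keel_height]]),
        -cfg.keel_half_depth, cfg.keel_half_depth, axis="y", n_layers=3)
    tray = trimesh.util.concatenate([plate, keel])

    insert = extrude_profile(
        concave_slab_profile(cfg.insert_half_depth, cfg.insert_top_above_axis,
                             cfg.dome_radius + cfg.clearance_mm, 0.0,
                             arc_points=cfg.arc_points),
        -cfg.insert_half_width, cfg.insert_half_width, axis="x",
        n_layers=cfg.mesh_layers)

    chord = cfg.dome_chord_z - cfg.dome_axis_z  # chord height above axis
    condyle = cylinder_segment_profile(cfg.dome_radius, cfg.dome_radius,
                                       chord, arc_points=cfg.arc_points)
    groove = cylinder_segment_profile(cfg.dome_radius - cfg.groove_depth,
                                      cfg.dome_radius - cfg.groove_depth,
                                      chord, arc_points=cfg.arc_points)
    g = cfg.groove_half_width
    parts = [
        extrude_profile(condyle, -cfg.dome_half_width, -g, axis="x",
                        n_layers=cfg.mesh_layers),
        extrude_profile(groove, -g, g, axis="x", n_layers=3),
        extrude_profile(condyle, g, cfg.dome_half_width, axis="x",
                        n_layers=cfg.mesh_layers),
    ]
    dome = trimesh.util.concatenate(parts)
    return tray, insert, dome


def _build_bone_meshes(cfg: PhantomConfig):
    tube = tube_mesh(cfg.tibia_outer_radius, cfg.tibia_inner_radius,
                     cfg.tibia_base_z, cfg.tibia_base_z + cfg.tibia_length,
                     sections=cfg.tube_sections, n_layers=cfg.mesh_layers)
    # medial malleolus: a flat process tangent to the shaft on the medial
    # side, running alongside the joint line
    medial = -1.0 if cfg.side == "left" else 1.0
    r = cfg.tibia_outer_radius
    x_in = medial * r
    x_out = medial * (r + cfg.malleolus_width)
    malleolus = extrude_profile(
        np.array(sorted([[min(x_in, x_out), -cfg.malleolus_half_depth],
                         [max(x_in, x_out), -cfg.malleolus_half_depth],
                         [max(x_in, x_out), cfg.malleolus_half_depth],
                         [min(x_in, x_out), cfg.malleolus_half_depth]],
                        key=lambda p: (np.arctan2(p[1], p[0])))),
        cfg.tibia_base_z, cfg.tibia_base_z + cfg.malleolus_height,
        axis="z", n_layers=3)
    r_at_crest = float(np.sqrt(max(r ** 2 - cfg.crest_half_width ** 2, 0.0)))
    crest = extrude_profile(
        np.array([[-cfg.crest_half_width, r_at_crest],
                  [cfg.crest_half_width, r_at_crest],
                  [cfg.crest_half_width, r + cfg.crest_height],
                  [-cfg.crest_half_width, r + cfg.crest_height]]),
        cfg.tibia_base_z + cfg.malleolus_height,
        cfg.tibia_base_z + cfg.tibia_length, axis="z", n_layers=3)
    tibia = trimesh.util.concatenate([tube, malleolus, crest])
    talus = extrude_profile(
        np.array([[-cfg.talus_half_depth, 0.0],
                  [cfg.talus_half_depth, 0.0],
                  [cfg.talus_half_depth, cfg.talus_height],
                  [-cfg.talus_half_depth, cfg.talus_height]]),
        -cfg.talus_half_width, cfg.talus_half_width, axis="x",
        n_layers=cfg.mesh_layers)
    return tibia, talus


def build_phantom(config: PhantomConfig | None = None, seed: int = 0
                  ) -> tuple[PhantomScene, CTVolume]:
    """Construct the full phantom scene and its CT-like volume.

    Deterministic for a fixed (config, seed); the seed drives only the
    metal-artifact texture and downstream stochastic helpers.
    """
    cfg = config or PhantomConfig()
    cfg.validate()

    tray, insert, dome = build_implant_meshes(cfg)
    tibia, talus = _build_bone_meshes(cfg)

    tray_to_tibia = RigidTransform(np.eye(3), [0, 0, cfg.tray_top_z], "cad", "ct")
    insert_to_tibia = RigidTransform(np.eye(3), [0, 0, cfg.dome_axis_z], "cad", "ct")
    dome_to_talus = RigidTransform(np.eye(3), [0, 0, cfg.dome_axis_z], "cad", "ct")

    tray_ct = tray.copy()
    tray_ct.apply_transform(tray_to_tibia.matrix)
    dome_ct = dome.copy()
    dome_ct.apply_transform(dome_to_talus.matrix)

    # Grid covering all geometry plus margin.
    lo = np.min([m.bounds[0] for m in (tibia, talus, tray_ct, dome_ct)], axis=0)
    hi = np.max([m.bounds[1] for m in (tibia, talus, tray_ct, dome_ct)], axis=0)
    lo -= cfg.margin_mm
    hi += cfg.margin_mm
    shape = np.maximum(np.ceil((hi - lo) / cfg.spacing_mm).astype(int) + 1, 2)
    grid = Grid(tuple(shape), [cfg.spacing_mm] * 3, lo)

    tibia_mask = mesh_to_binary_stack(tibia, grid)
    talus_mask = mesh_to_binary_stack(talus, grid)
    if cfg.include_implants:
        tray_mask = mesh_to_binary_stack(tray_ct, grid)
        dome_mask = mesh_to_binary_stack(dome_ct, grid)
    else:
        tray_mask = np.zeros(grid.shape, dtype=bool)
        dome_mask = np.zeros(grid.shape, dtype=bool)

    # initial segmentation: cortical bone adjacent to metal cannot be
    # outlined, so the masks stop short of the implants
    implant_all = tray_mask | dome_mask
    if implant_all.any() and cfg.segmentation_gap_mm > 0:
        d_imp = ndimage.distance_transform_edt(~implant_all,
                                               sampling=grid.spacing)
        keep = d_imp > cfg.segmentation_gap_mm
        tibia_mask_initial = tibia_mask & keep
        talus_mask_initial = talus_mask & keep
    else:
        tibia_mask_initial = tibia_mask.copy()
        talus_mask_initial = talus_mask.copy()

    intensities = np.zeros(grid.shape, dtype=np.float32)
    # soft-tissue envelope: padded cylinder around everything
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    cx, cy = (lo[:2] + hi[:2]) / 2.0
    renv = max((hi[0] - lo[0]), (hi[1] - lo[1])) / 2.0 - 1.0
    soft = (xs - cx) ** 2 + (ys - cy) ** 2 <= renv ** 2
    intensities[np.broadcast_to(soft, grid.shape)] = cfg.soft_tissue_intensity

    # bones: trabecular interior, cortical within cortical_thickness of surface
    for mask in (tibia_mask, talus_mask):
        if not mask.any():
            continue
        depth = ndimage.distance_transform_edt(mask, sampling=grid.spacing)
        intensities[mask] = np.where(
            depth[mask] <= cfg.cortical_thickness,
            cfg.cortical_intensity, cfg.trabecular_intensity)
    # medullary canal reads trabecular
    canal = _canal_mask(cfg, grid)
    intensities[canal & ~tibia_mask] = cfg.trabecular_intensity
    implant_mask = tray_mask | dome_mask
    intensities[implant_mask] = cfg.implant_intensity

    clean = CTVolume(intensities, grid.spacing, grid.origin)
    volume = clean.copy()
    if cfg.include_implants and cfg.artifact_strength > 0:
        volume = simulate_metal_artifact(volume, implant_mask,
                                         cfg.artifact_strength,
                                         band_mm=cfg.artifact_band_mm,
                                         seed=seed)

    scene = PhantomScene(cfg, seed, volume, clean, tibia, talus, tray, insert,
                         dome, tray_to_tibia, insert_to_tibia, dome_to_talus,
                         tibia_mask, talus_mask, tray_mask, dome_mask,
                         tibia_mask_initial, talus_mask_initial)
    return scene, volume


def _canal_mask(cfg: PhantomConfig, grid: Grid) -> np.ndarray:
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    zs = grid.axis_centers(2)[None, None, :]
    return ((xs ** 2 + ys ** 2 <= cfg.tibia_inner_radius ** 2)
            & (zs >= cfg.tibia_base_z)
            & (zs <= cfg.tibia_base_z + cfg.tibia_length))


# ---------------------------------------------------------------------------
# Metal artifact
# ---------------------------------------------------------------------------

def simulate_metal_artifact(volume: CTVolume, implant_mask: np.ndarray,
                            strength: float, band_mm: float = 6.0,
                            seed: int = 0) -> CTVolume:
    """Add streak/bloom intensity corruption in a band around the implants.

    Radial in-plane streaks (axial slices, matching CT reconstruction
    geometry) and a Gaussian bloom halo are added only where the distance
    to an implant voxel is within ``band_mm``; everything farther is
    returned bit-exact.  Mimics residual artifact after vendor metal
    artifact reduction — the reason bone near the implant cannot be
    segmented directly.
    """
    if strength < 0:
        raise ValueError("artifact strength must be non-negative")
    implant_mask = np.asarray(implant_mask, dtype=bool)
    if implant_mask.shape != volume.intensities.shape:
        raise ValueError("implant mask shape does not match volume")
    out = volume.copy()
    if strength == 0 or not implant_mask.any():
        return out
    rng = np.random.default_rng(seed)
    grid = volume.grid
    dist = ndimage.distance_transform_edt(~implant_mask, sampling=grid.spacing)
    band = (dist > 0) & (dist <= band_mm)

    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    idx = np.nonzero(implant_mask)
    # per-slice implant centroid (fall back to global centroid)
    gx, gy = xs[idx[0]].mean(), ys[idx[1]].mean()
    corruption = np.zeros(grid.shape, dtype=np.float32)
    n_spokes = 13
    phase = rng.uniform(0, 2 * np.pi)
    for k in range(grid.shape[2]):
        sl = implant_mask[:, :, k]
        if sl.any():
            ii, jj = np.nonzero(sl)
            cx, cy = xs[ii].mean(), ys[jj].mean()
        else:
            cx, cy = gx, gy
        theta = np.arctan2(ys[None, :] - cy, xs[:, None] - cx)
        streak = np.cos(n_spokes * theta + phase)
        corruption[:, :, k] = streak
    decay = np.exp(-dist / max(band_mm / 2.0, 1e-6))
    bloom = ndimage.gaussian_filter(
        implant_mask.astype(np.float32), sigma=2.0 / grid.spacing) * 400.0
    corruption = (corruption * 250.0 * decay + bloom) * strength
    out.intensities[band] += corruption[band]
    return out


# ---------------------------------------------------------------------------
# Gait trajectory
# ---------------------------------------------------------------------------

def _stance_angle_curves(s: np.ndarray, rng: np.random.Generator,
                         noise_deg: float) -> dict:
    """Smooth tibiotalar angle curves over stance fraction s in [0, 1]:
    plantarflexion after heel strike, progressive dorsiflexion through
    late stance, plantarflexion into toe off."""
    df = CubicSpline([0.0, 0.12, 0.45, 0.8, 1.0],
                     [0.0, -6.0, 1.0, 8.0, -2.0],
                     bc_type=((1, 0.0), (1, 0.0)))(s)
    inv = 2.0 * np.sin(np.pi * s) * np.cos(np.pi * s * 1.5)
    ir = 3.0 * np.sin(np.pi * s) ** 2
    if noise_deg > 0:
        for arr in (df, inv, ir):
            k = rng.integers(2, 5)
            ph = rng.uniform(0, 2 * np.pi)
            arr += noise_deg * np.sin(2 * np.pi * k * s + ph)
    return {"dorsiflexion": df, "inversion": inv, "internal_rotation": ir}


def _force_profile(s: np.ndarray, peak_n: float) -> np.ndarray:
    """Double-hump vertical ground reaction force over stance fraction."""
    shape = np.sin(np.pi * s) * (1.0 + 0.25 * np.cos(2 * np.pi * s))
    return peak_n * shape / shape.max()


def gs_rotation_from_angles(dorsiflexion_deg: float, inversion_deg: float,
                            internal_deg: float, tibia_basis: np.ndarray,
                            talus_basis: np.ndarray, side: str) -> np.ndarray:
    """Relative rotation (talus w.r.t. tibia, model coords) that the
    joint-coordinate-system decomposition maps back to the given angles.

    Inverse companion of :func:`tartrack.kinematics.grood_suntay`; the
    bases have columns (ML, AP, SI)."""
    s = 1.0 if side == "right" else -1.0
    a = np.radians(dorsiflexion_deg)
    b = np.radians(-s * inversion_deg)
    c = np.radians(-s * internal_deg)
    A = _working_basis(tibia_basis)
    B = _working_basis(talus_basis)
    Q = (_rot_axis([1, 0, 0], a) @ _rot_axis([0, 1, 0], b)
         @ _rot_axis([0, 0, 1], c))
    return A @ Q @ B.T


def _working_basis(basis: np.ndarray) -> np.ndarray:
    """Right-handed working triple: flip ML for left-handed frames."""
    basis = np.asarray(basis, dtype=float)
    if np.linalg.det(basis) < 0:
        basis = basis.copy()
        basis[:, 0] = -basis[:, 0]
    return basis


def synthesize_gait_trajectory(scene: PhantomScene, seed: int = 0,
                               n_stance_frames: int | None = None,
                               frame_rate_hz: float | None = None
                               ) -> GroundTruthTrajectory:
    """Ground-truth stance-phase trajectory for tibia and talus.

    The tibia sways and progresses slightly; the talus moves relative to it
    by joint rotations composed about the dome cylinder axis (so the
    articulation stays congruent) plus a small anterior-posterior drift.
    The force trace crosses 5 % of its maximum exactly twice.
    """
    cfg = scene.config
    rng = np.random.default_rng(seed)
    fs = frame_rate_hz or cfg.frame_rate_hz
    if cfg.stance_duration_s <= 0:
        raise ValueError("stance duration must be positive")
    n_st = n_stance_frames or max(2, int(round(cfg.stance_duration_s * fs)))
    pad = cfg.n_pad_frames
    s = np.linspace(0.0, 1.0, n_st)
    angles = _stance_angle_curves(s, rng, cfg.angle_noise_deg)
    force_st = _force_profile(s, cfg.peak_force_n)

    n_total = n_st + 2 * pad
    full = {k: np.concatenate([np.full(pad, v[0]), v, np.full(pad, v[-1])])
            for k, v in angles.items()}
    force = np.concatenate([np.zeros(pad), force_st, np.zeros(pad)])
    time_s = np.arange(n_total) / fs

    tib_basis, tal_basis = scene.analytic_frame_bases()
    axis_center = np.array([0.0, 0.0, cfg.dome_axis_z])

    # tibia global motion: gentle progression and shank tilt
    sf = np.concatenate([np.zeros(pad), s, np.ones(pad)])
    tilt = np.radians(-4.0 + 8.0 * sf)
    prog_y = 6.0 * (sf - 0.5)
    lift_z = 1.5 * np.sin(np.pi * sf)

    tibia_poses, talus_poses = [], []
    for i in range(n_total):
        R_t = _rot_axis([1, 0, 0], tilt[i])
        t_t = np.array([0.0, prog_y[i], lift_z[i]])
        # rotate the shank about the joint center, not the volume origin
        t_t = t_t + axis_center - R_t @ axis_center
        P_tib = Pose(RigidTransform(R_t, t_t, "ct", "mbt"), i, fs)

        R_rel = gs_rotation_from_angles(
            full["dorsiflexion"][i], full["inversion"][i],
            full["internal_rotation"][i], tib_basis, tal_basis, cfg.side)
        drift = np.array([0.0, 0.8 * np.sin(np.pi * sf[i]), 0.0])
        t_rel = axis_center + drift - R_rel @ axis_center
        T_rel = RigidTransform(R_rel, t_rel, "ct", "ct")
        P_tal_T = P_tib.transform.rotation @ T_rel.rotation
        P_tal_t = (P_tib.transform.rotation @ T_rel.translation
                   + P_tib.transform.translation)
        talus_poses.append(Pose(RigidTransform(P_tal_T, P_tal_t, "ct", "mbt"),
                                i, fs))
        tibia_poses.append(P_tib)

    traj = GroundTruthTrajectory(
        tibia_poses, talus_poses, force, time_s, full,
        stance_start=pad, stance_end=pad + n_st - 1,
        tibia_frame_basis=tib_basis, talus_frame_basis=tal_basis,
        frame_rate_hz=fs)
    _check_continuity(traj)
    return traj


def _check_continuity(traj: GroundTruthTrajectory) -> None:
    from .geometry import rotation_angle_deg
    scale = traj.frame_rate_hz / 200.0
    for poses in (traj.tibia_poses, traj.talus_poses):
        for a, b in zip(poses, poses[1:]):
            dr = rotation_angle_deg(a.rotation.T @ b.rotation)
            dt = np.linalg.norm(b.translation - a.translation)
            if dr * scale > 3.0 or dt * scale > 3.0:
                warnings.warn("trajectory discontinuity exceeds the 200 Hz "
                              "continuity budget", stacklevel=3)
                return


# ---------------------------------------------------------------------------
# Fluoroscopy rendering
# ---------------------------------------------------------------------------

def render_fluoro_sequence(scene: PhantomScene,
                           trajectory: GroundTruthTrajectory,
                           cameras: tuple[CameraModel, CameraModel],
                           poisson_noise: bool = False,
                           noise_scale: float = 2.0e-4,
                           photons: float = 5.0e4,
                           seed: int = 0) -> list[np.ndarray]:
    """Render the biplane image sequences of the moving phantom.

    Each frame is the sum of the line-integral projections of the two rigid
    complexes (tibia+tray, talus+dome) at their ground-truth poses.
    Optional Poisson noise models quantum mottle: the integral is
    exponentiated to a transmitted-photon count, Poisson-sampled, and
    log-converted back.  Returns ``[stack_cam1, stack_cam2]`` with shape
    (n_frames, rows, cols).
    """
    if len(cameras) != 2:
        raise ValueError("biplane rendering needs exactly two cameras")
    _warn_if_not_orthogonal(cameras)
    rng = np.random.default_rng(seed)
    from .geometry import compose
    components = [(scene.bone_volume("tibia"), None, "tibia"),
                  (scene.bone_volume("talus"), None, "talus")]
    if scene.config.include_implants:
        # antialiased rasterization: a physical metal part has a
        # continuous boundary, so the rendered implant silhouette must not
        # carry the grid-phase quantization of a binary voxelization
        components += [
            (scene.implant_solid_volume("tray"), scene.tray_to_tibia, "tibia"),
            (scene.implant_solid_volume("dome"), scene.dome_to_talus, "talus"),
        ]
    stacks = []
    for cam in cameras:
        frames = np.zeros((trajectory.n_frames, cam.n_rows, cam.n_cols),
                          dtype=np.float32)
        for i in range(trajectory.n_frames):
            body_pose = {"tibia": trajectory.tibia_poses[i].transform,
                         "talus": trajectory.talus_poses[i].transform}
            img = np.zeros((cam.n_rows, cam.n_cols), dtype=np.float32)
            for vol, placement, body in components:
                pose = (body_pose[body] if placement is None
                        else compose(body_pose[body], placement))
                img += project_volume(vol.intensities, vol.grid, pose, cam)
            if img.max() == 0:
                warnings.warn(f"frame {i}: object outside the view frustum",
                              stacklevel=2)
            if poisson_noise:
                transmitted = photons * np.exp(-noise_scale * img)
                counts = rng.poisson(transmitted).astype(np.float64)
                counts = np.maximum(counts, 1.0)
                img = (-np.log(counts / photons) / noise_scale).astype(np.float32)
            frames[i] = img
        stacks.append(frames)
    return stacks


def _warn_if_not_orthogonal(cameras) -> None:
    d1 = cameras[0].normal
    d2 = cameras[1].normal
    ang = np.degrees(np.arccos(np.clip(abs(np.dot(d1, d2)), 0, 1)))
    if ang < 60.0:
        warnings.warn("biplane cameras are far from orthogonal "
                      f"(axis separation {90 - ang:.0f} deg from 90)",
                      stacklevel=3)
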