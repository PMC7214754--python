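"""Hybrid bone/implant model construction.

Metal artifact prevents segmenting the implant (and the adjacent bone)
from CT, so each implant's CAD geometry is welded to its bone as one rigid
body instead:

1. every object (bone, implant) is tracked individually over a short
   static standing trial and the per-frame poses are averaged into a mean
   static definition;
2. the implant-to-bone link transform is obtained by chaining the
   CT→global and global→tracking transforms of both objects and inverting
   the bone's chain, landing the implant in the bone's CT space;
3. the bone mask is re-segmented at the interface, adding bone material
   across the artifact-induced gap up to the implant boundary so the DRR
   shows a solid bone-implant interface (false internal edges break the
   edge-based tracker);
4. the conditioned bone DRR and the hollowed, intensity-magnified implant
   DRR are merged into a single hybrid DRR volume that is tracked as one
   rigid body from then on.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
import yaml
from scipy import ndimage

from .drr import DRRVolume, condition_intensities
from .geometry import (CoordinateFrame, Pose, RigidTransform, average_poses,
                       compose, invert, standard_frame, transform_ct_to_global,
                       GLOBAL_FRAME)
from .tracking import track_frame
from .volume import Grid, GridMismatchError

__all__ = ["HybridModel", "InterfaceOverlapError", "StaticTrackingError",
           "register_static", "link_implant_to_bone", "fill_interface",
           "assemble_hybrid_drr"]

#: Default maximum interface gap bridged by re-segmentation, mm.
DEFAULT_MAX_GAP_MM = 3.0


class InterfaceOverlapError(ValueError):
    """Bone and implant masks overlap: the link transform is implausible."""


class StaticTrackingError(RuntimeError):
    """Raised when too many static frames fail to track."""


@dataclass
class HybridModel:
    """One bone welded to its implant: meshes, masks, link and hybrid DRR."""

    bone_mesh: trimesh.Trimesh
    bone_mask: np.ndarray
    implant_mesh: trimesh.Trimesh
    implant_mask_hollow: np.ndarray
    link: RigidTransform          # implant CAD space -> bone CT space
    drr: DRRVolume                # combined hybrid DRR
    side: str = "left"

    def __post_init__(self):
        if self.drr.provenance != "hybrid":
            raise ValueError("hybrid model requires a hybrid-provenance DRR")

    def save(self, directory) -> None:
        """Bundle on disk: meshes (STL), masks/DRR (NIfTI), link (JSON),
        manifest (YAML)."""
        from .volume import CTVolume
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.bone_mesh.export(d / "bone.stl")
        self.implant_mesh.export(d / "implant.stl")
        g = self.drr.grid
        CTVolume(self.bone_mask.astype(np.float32), g.spacing, g.origin
                 ).to_nifti(d / "bone_mask.nii.gz")
        CTVolume(self.implant_mask_hollow.astype(np.float32), g.spacing,
                 g.origin).to_nifti(d / "implant_mask_hollow.nii.gz")
        CTVolume(self.drr.intensities, g.spacing, g.origin
                 ).to_nifti(d / "hybrid_drr.nii.gz")
        (d / "link.json").write_text(self.link.to_json())
        manifest = {
            "side": self.side,
            "drr_provenance": self.drr.provenance,
            "grid_shape": list(g.shape),
            "spacing_mm": g.spacing.tolist(),
            "origin_mm": g.origin.tolist(),
            "files": ["bone.stl", "implant.stl", "bone_mask.nii.gz",
                      "implant_mask_hollow.nii.gz", "hybrid_drr.nii.gz",
                      "link.json"],
        }
        (d / "manifest.yaml").write_text(yaml.safe_dump(manifest))

    @classmethod
    def load(cls, directory) -> "HybridModel":
        from .volume import CTVolume
        d = Path(directory)
        manifest = yaml.safe_load((d / "manifest.yaml").read_text())
        drr_vol = CTVolume.from_nifti(d / "hybrid_drr.nii.gz")
        return cls(
            bone_mesh=trimesh.load(d / "bone.stl"),
            bone_mask=CTVolume.from_nifti(d / "bone_mask.nii.gz").intensities > 0.5,
            implant_mesh=trimesh.load(d / "implant.stl"),
            implant_mask_hollow=CTVolume.from_nifti(
                d / "implant_mask_hollow.nii.gz").intensities > 0.5,
            link=RigidTransform.from_json((d / "link.json").read_text()),
            drr=DRRVolume(drr_vol.intensities, drr_vol.grid, "hybrid"),
            side=manifest["side"],
        )


# ---------------------------------------------------------------------------
# Static registration
# ---------------------------------------------------------------------------

def register_static(drr: DRRVolume, frames, cameras, init: Pose,
                    seed: int = 0, max_failure_fraction: float = 0.5,
                    **track_kwargs) -> Pose:
    """Mean static pose of one object over up to 20 static-trial frames.

    ``frames`` is a list of biplane image pairs.  Each pair is tracked
    independently (warm-started from the previous solution) and the
    per-frame poses are averaged; an error is raised when more than half
    the frames end above the review threshold.
    """
    if not 1 <= len(frames) <= 20:
        raise ValueError("static registration expects 1-20 frame pairs")
    poses, flags = [], []
    current = init
    for i, pair in enumerate(frames):
        pose, _cost, flag = track_frame(drr, pair, cameras, current,
                                        seed=seed + i, **track_kwargs)
        poses.append(pose)
        flags.append(flag["review"])
        current = pose
    if np.mean(flags) > max_failure_fraction:
        raise StaticTrackingError(
            f"{int(np.sum(flags))}/{len(flags)} static frames failed tracking")
    return average_poses(poses)


# ---------------------------------------------------------------------------
# Link transform (Eq 1-4 chain)
# ---------------------------------------------------------------------------

def _ct_to_mbt_chain(pose: Pose, ct_frame: CoordinateFrame,
                     global_frame: CoordinateFrame) -> RigidTransform:
    """Full CT→tracking transform built through the global frame."""
    t_ct_g = transform_ct_to_global(ct_frame, global_frame)
    src = pose.transform.source_space
    # global→MBT from the tracked placement, expressed via the chain
    t_g_mbt = compose(pose.transform, invert(
        RigidTransform(t_ct_g.rotation, t_ct_g.translation, src, "global")))
    return compose(t_g_mbt, RigidTransform(
        t_ct_g.rotation, t_ct_g.translation, src, "global"))


def link_implant_to_bone(bone_pose: Pose, implant_pose: Pose,
                         bone_ct_frame: CoordinateFrame | None = None,
                         implant_ct_frame: CoordinateFrame | None = None,
                         global_frame: CoordinateFrame = GLOBAL_FRAME
                         ) -> RigidTransform:
    """Implant-to-bone link from the mean static poses.

    Chains CT→global and global→tracking for both objects, then inverts
    the bone's chain so the implant lands in the bone's CT space:
    ``link = (T_CT→MBT,bone)⁻¹ ∘ T_CT→MBT,implant``.  Bounding-box CT
    frames default to standard-basis frames at the origin (for which the
    CT→global rotation is exactly the identity).
    """
    bone_ct_frame = bone_ct_frame or standard_frame(
        label=bone_pose.transform.source_space)
    implant_ct_frame = implant_ct_frame or standard_frame(
        label=implant_pose.transform.source_space)
    t_bone = _ct_to_mbt_chain(bone_pose, bone_ct_frame, global_frame)
    t_implant = _ct_to_mbt_chain(implant_pose, implant_ct_frame, global_frame)
    return compose(invert(t_bone), t_implant)


# ---------------------------------------------------------------------------
# Interface re-segmentation
# ---------------------------------------------------------------------------

def fill_interface(bone_mask: np.ndarray, implant_mask: np.ndarray,
                   spacing_mm, max_gap_mm: float = DEFAULT_MAX_GAP_MM,
                   max_iterations: int = 20) -> np.ndarray:
    """Re-segment the bone/implant interface: relabel as bone the
    background voxels lying in the gap band (within ``max_gap_mm`` of both
    masks, connected to the bone, outside the implant).

    The band fill is iterated to its fixed point, which makes the
    operation idempotent.  A gap wider than ``max_gap_mm`` is left
    unchanged with a warning; overlapping input masks raise, since an
    implant inside the bone interior signals a bad link transform.
    """
    bone = np.asarray(bone_mask, dtype=bool).copy()
    implant = np.asarray(implant_mask, dtype=bool)
    if bone.shape != implant.shape:
        raise GridMismatchError("bone and implant masks on different grids")
    if (bone & implant).any():
        raise InterfaceOverlapError(
            "bone and implant masks overlap before interface fill")
    spacing = np.broadcast_to(np.asarray(spacing_mm, float), (3,))
    d_imp = ndimage.distance_transform_edt(~implant, sampling=spacing)
    added_any = False
    for _ in range(max_iterations):
        d_bone = ndimage.distance_transform_edt(~bone, sampling=spacing)
        candidate = (~bone & ~implant
                     & (d_bone <= max_gap_mm) & (d_imp <= max_gap_mm))
        if not candidate.any():
            break
        # keep only candidate regions reachable from the bone surface
        labels, _n = ndimage.label(candidate | bone)
        bone_labels = np.unique(labels[bone])
        keep = candidate & np.isin(labels, bone_labels)
        if not keep.any():
            break
        bone |= keep
        added_any = True
    else:
        warnings.warn("interface fill did not reach a fixed point within "
                      f"{max_iterations} iterations", stacklevel=2)
    if not added_any and not (ndimage.binary_dilation(bone) & implant).any():
        warnings.warn("no interface voxels filled: gap wider than max_gap_mm "
                      "or masks already in contact", stacklevel=2)
    return bone


# ---------------------------------------------------------------------------
# Hybrid DRR assembly
# ---------------------------------------------------------------------------

def assemble_hybrid_drr(bone_drr: DRRVolume, implant_drr_hollowed: DRRVolume,
                        link: RigidTransform,
                        max_clipped_fraction: float = 0.01,
                        condition: bool = True) -> DRRVolume:
    """Merge the bone DRR with the linked, hollowed implant DRR.

    The implant volume is resampled into the bone grid through ``link``
    with nearest-neighbor interpolation (preserving the binary edge), both
    are intensity-conditioned (bone ×0.6; implant edge set to the
    magnified uniform value), and merged — summed where disjoint, implant
    winning where coincident.
    """
    bone = condition_intensities(bone_drr, "bone") if condition else bone_drr
    implant = (condition_intensities(implant_drr_hollowed, "implant")
               if condition else implant_drr_hollowed)

    bgrid = bone.grid
    igrid = implant.grid
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in bgrid.shape), indexing="ij")
    world = np.stack([ii, jj, kk], axis=-1) * bgrid.spacing + bgrid.origin
    inv = invert(link)
    impl_coords = (world.reshape(-1, 3) @ inv.rotation.T + inv.translation
                   - igrid.origin) / igrid.spacing
    resampled = ndimage.map_coordinates(
        implant.intensities, impl_coords.T, order=0, mode="constant",
        cval=0.0, prefilter=False).reshape(bgrid.shape)

    # clipped fraction: implant support that falls outside the bone grid
    sup = np.stack(np.nonzero(implant.intensities), axis=1)
    if sup.size:
        sup_world = igrid.voxel_to_world(sup) @ link.rotation.T + link.translation
        vox = (sup_world - bgrid.origin) / bgrid.spacing
        outside = np.any((vox < -0.5) | (vox > np.array(bgrid.shape) - 0.5),
                         axis=1)
        frac = float(outside.mean())
        if frac > max_clipped_fraction:
            raise ValueError(
                f"resampled implant exits the bone grid: {frac:.1%} clipped")

    merged = np.where(resampled > 0, resampled,
                      bone.intensities).astype(np.float32)
    return DRRVolume(merged, bgrid, "hybrid")
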