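# Methods

`tartrack` measures the 6-DOF motion of a replaced (prosthetic) tibiotalar
joint from biplane fluoroscopy. The obstacle it is built around is metal
artifact: CT of an ankle after total ankle replacement (TAR) cannot be
segmented reliably near the implants, so neither the implants nor the
adjacent cortical bone are directly available as tracking models. The
package's answer is the *hybrid model*: each bone is welded to its
implant's CAD geometry as one rigid body, registered once during a static
standing trial, and tracked as a unit thereafter.

## Coordinate systems and transforms

Three spaces are used throughout: **CT/model space** (millimetre
coordinates of the segmented volume, or of an implant's CAD file),
**global space** (the standard basis at the origin) and **tracking (MBT)
space** (the laboratory frame of the two fluoroscopes). A transform
between frames A and B is the frame-alignment map `T_A→B = F_B ∘ F_A⁻¹`
with `F_X(x) = O_X + basis_Xᵀ x`; for bounding-box CT frames, which share
the standard global basis, the CT→global rotation is exactly the identity
and the translation is the origin difference. Transforms carry mandatory
space labels ("ct", "global", "mbt", "cad") so that mis-chained
compositions fail loudly rather than silently.

Static-trial poses are averaged into a "mean static definition":
translations arithmetically, rotations by the quaternion eigen-mean
(principal eigenvector of the sum of sign-aligned quaternion outer
products), re-orthonormalized to 1e-9. A warning is raised when the
rotations to be averaged are spread more than 30°, which would violate the
static-trial assumption.

## Hybrid model construction

1. **Binary stacks.** Surfaces become slice-by-slice binary volumes by a
   voxel-center in/out test (vertical-ray crossing parity, jittered rays).
2. **Bone isolation.** Bone DRR intensity = CT × mask, element-wise.
3. **Implant hollowing.** Implant stacks keep only each slice's 2-D
   boundary (`in AND NOT erode2D(in)`, 4-connected), mimicking the dense
   cortical shell; regions too thin to erode pass through unchanged.
4. **Static registration and linking.** Each object (two bones, two metal
   components) is tracked over 1–20 static frames; the implant-to-bone
   link is `(T_CT→MBT,bone)⁻¹ ∘ T_CT→MBT,implant`, landing the implant in
   its bone's CT space.
5. **Interface re-segmentation.** Background voxels within `max_gap_mm`
   (default 3 mm) of both the bone and the linked implant, connected to
   the bone, are relabeled bone; the band fill is iterated to its fixed
   point, which makes the operation idempotent. Overlapping input masks
   raise — an implant inside the bone interior means a bad link.
6. **Hybrid DRR.** The bone DRR (dimmed to 60 %) and the hollowed implant
   (set to a uniform reference of 30 and magnified ×100, i.e. metal-CT
   brightness) merge on the bone grid, the implant resampled
   nearest-neighbor so its binary edge survives; the implant wins
   coincident voxels.

"Decreased by 0.6" is read multiplicatively (retain 60 %); the
subtractive reading (retain 40 %) is available as a configuration option.

## Tracking

A candidate pose is scored by rendering the model into both calibrated
views (perspective line integrals, trilinear sampling along
source-to-pixel rays) and comparing Sobel edge images against the target
frames with normalized cross-correlation; the cost is `1 − mean NCC`,
in [0, 2]. Optimization is a seeded multi-start Nelder-Mead direct search
over (tx, ty, tz, rx, ry, rz) — rotations as small axis-angle increments
about the object's centroid — warm-started frame to frame. Three details
matter in a multi-body scene:

* **Attention windows.** The correlation is restricted to the model's
  projected footprint at the initialization, dilated to cover the capture
  range: the automated counterpart of an operator concentrating on one
  structure.
* **Residual images.** Biplane frames are sums of overlapping
  projections, so each object is optimized against residuals: the other
  objects, rendered at their current estimates and least-squares
  intensity-scaled per view, are subtracted first. Objects alternate for
  two sweeps per frame. This replaces the interactive 3-D review loop of
  the original workflow; automated convergence and review flags plus a
  machine-readable review report stand in for visual checks.
* **Capture range as a constraint.** The initialization contract
  (≤ 5 mm / 5°) is enforced by a soft quadratic penalty beyond ±6 mm / 6°.
  Without it, near-symmetric implant shapes (a flat tray is close to
  square) can jump to distant self-similar basins.
* **Metal-neighborhood exclusion.** When a *bone* is registered in the
  static trial, the implants' dilated projected footprints are removed
  from its attention window: the initial segmentation is unreliable next
  to metal (its boundary stops short of the implant), so the bone pose
  must come from clean diaphyseal and peripheral edges — as an operator
  would align it.
* **Velocity-predicted warm starts.** Frame t initializes from a
  constant-velocity extrapolation of the t−1 and t−2 solutions, which
  keeps the residual subtraction fresh and the optimizer within a
  fraction of a millimetre of the optimum during stance.

The matcher used by the pipeline is an *unconditioned compound* model:
the bone volume at CT intensities plus the solid implant on its own fine
CAD grid, projections summed. The conditioned hollow-edge hybrid DRR is
built, stored and exported as the model bundle's rendering artifact, but
on the phantom its correlation against solid-metal radiographs proved
biased and multi-modal; the compound model is the renderable that
actually predicts the image. Implant solids are rasterized with
antialiased fractional occupancy (a supersampled in/out test), so their
projected silhouettes are accurate to a fraction of a voxel and free of
grid-phase quantization — without this, the weakly constrained axial
rotations absorb sub-pixel silhouette offsets as degree-level pose bias.

## Verification by articular distance

The polyethylene insert is invisible on fluoroscopy but rigidly fixed to
the tray (fixed-bearing design), so it rides along with the tracked
tibial hybrid. Per frame, signed closest-point distances are computed
from the insert's selected articular face to the talar component surface
(negative = penetration, positive = gap; sign from watertight
containment). The per-frame *mean* must stay strictly inside
(−0.5 mm, +1.5 mm): small penetrations are tolerated because the real
polymer deforms slightly, larger ones or wide gaps mean the 3-D solution
is implausible. Per-vertex extremes are reported but not gating. The
trial passes only if every frame passes; this per-frame gating is the
stricter of the two readings of "an average … was evaluated".

## Anatomical frames and kinematics

The tibial medial-lateral axis comes from a least-squares cylinder fit to
the articular surface of the tibial component (axis seeded from each
principal direction of the cloud, best fit kept); a tibial-shaft cylinder
gives a temporary superior-inferior axis; two successive cross products
complete the triple, and the origin is the ML-axis base translated along
SI onto the implant base plane. The talar frame fits the dome curvature,
offsets the ML line a quarter radius toward the implant base plane, and
uses anterior/posterior landmark splines for the temporary AP direction.

Left limbs carry a left-handed basis and right limbs a right-handed one,
with v_ML medial, v_AP anterior and v_SI superior on both sides; this is
achieved by evaluating the cross products with a *handed* cross
(right-hand rule on the right, negated on the left). In the joint
coordinate system (body-fixed tibial ML, body-fixed talar SI, floating
axis), angles are extracted as an intrinsic Cardan sequence in a
right-handed working basis (ML flipped for left-handed frames), with
signs arranged so dorsiflexion, inversion and internal rotation are
positive on both limbs. The decomposition and its recomposition are exact
inverses to machine precision; alignment of the two body-fixed axes
(gimbal) raises an error.

Angles are filtered with a zero-phase Butterworth low-pass: a
second-order design run forward and backward (effective fourth order —
the chosen reading of "fourth-order bidirectional"; an effective
eighth-order variant is a configuration flag), cutoff 10 Hz by default or
selected by Winter-style residual analysis (0.5 Hz candidate grid, linear
fit to the high-frequency tail, lowest candidate reaching the noise
floor; a small floor proportional to the signal's scale keeps the rule
defined for noiseless inputs). Gait events come from the vertical ground
reaction force: 5 % of the trace maximum with a 10 ms debounce; heel
strike is the first sample of the first surviving supra-threshold run,
toe off the last sample of the last. Angle curves are then linearly
resampled to 101 points over 0–100 % stance. The pipeline order is fixed:
angles → filter → normalize.

## Wear projection

The closed-form polyethylene wear estimate converts an in vitro
volumetric wear rate (3.3 mm³ per megacycle for this design) to an annual
volume via an assumed 5 000 steps/day (= 1.825 Mc/year over a 365-day
year, chosen to be an overestimate), then to a mean linear depth by
dividing by the articular contact area (945 mm² for the studied implant
size). At 1.5 and 10 years the depths are ~0.01 and ~0.06 mm — an order
of magnitude below fluoroscopic tracking precision, which is why wear
does not invalidate using pristine CAD geometry for tracking.

## The synthetic phantom

The phantom emulates the study conditions end to end: a CT-like volume
(0.6 mm isotropic by default) with cortical shell / trabecular /
soft-tissue / metal intensity tiers; parametric implant stand-ins (tray =
plate + keel, insert = slab with a concave cylindrical inferior face,
dome = bicondylar cylinder segments with a shallow central groove) at
millimetre scales typical of TAR; a stance-phase trajectory at 200 Hz
built by composing joint-coordinate-system rotations about the dome axis
(so the articulation stays congruent at the designed 1 mm radial
clearance) with a double-hump vertical force trace crossing its 5 %
threshold exactly twice; and biplane sequences rendered by the same ray
caster the tracker uses (608×600 at full scale), with optional seeded
Poisson noise.

Deliberate realism choices: the physical bone is continuous up to the
implant and only the *initial* segmentation masks stop 1.8 mm short of
the metal (that is the problem re-segmentation solves); metal artifact
(radial streaks + bloom, confined to a 6 mm band) corrupts the CT volume
but not the fluoroscopy frames; implants are rendered from their own
fine CAD grids, as physical parts with continuous boundaries; and the
tibia carries a medial-malleolus process and an anterior shaft crest,
without which a tubular shaft is rotationally symmetric and axial
rotation would be unobservable — as it is not on a real distal tibia.

What the phantom does *not* model: realistic X-ray physics (scatter,
beam hardening spectra), image-intensifier distortion, soft-tissue
occlusion of edges, swing-phase gait, and real anatomical shape
complexity. Passing tests therefore demonstrate the internal consistency
and numerical correctness of the workflow under ideal-projection
conditions, not clinical accuracy on patient data.

## Problem sizes and numerical choices

Desk-scale defaults run the full pipeline in minutes on one CPU: 1.2 mm
phantom voxels, 160×160 px views over a 120 mm field, 20 stance frames at
28.6 Hz (the 0.7 s stance retimed), 2 static frames, and ray sampling at
each component volume's own voxel size. Full-scale parameters (0.6 mm CT, 200 Hz, 608×600)
are configuration values, not code changes. Other numerical choices:
voxel-center rasterization without anti-aliasing; nearest-neighbor
implant resampling in the stored hybrid DRR; optimizer convergence at
1e-6 cost improvement with a review flag above 0.35 (single-object
images) or a configured threshold in cluttered scenes; strict
inequalities at the distance-band boundaries; ties at coincident hybrid
voxels resolved in favor of the implant.

## Known limitations

* Rotation about an implant's own symmetry axis (e.g. the dome cylinder,
  the near-square tray plate) is intrinsically weakly observable: link
  translations recover to well under 0.2 mm on the phantom while link
  rotations about those axes sit near 1°. The surrounding bone supplies
  most of the constraint downstream, which is exactly why hybrid models
  outperform implant-only tracking for symmetric designs.
* The tracker is local: the capture-range precondition (≤ 5 mm / 5°) is a
  contract on the initialization, softly enforced, not removed.
* Distance-map verification checks geometric plausibility of the tracked
  solution, not contact mechanics; the polymer is treated as rigid.
* Only phantom mode is wired end-to-end in `run_pipeline`; externally
  acquired data can be processed stage by stage through the library and
  CLI subcommands.
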