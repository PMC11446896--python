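# Methods

## Scope and model

`zygoplan` implements the computational chain for planning a secondary
(re-)positioning of a malunited zygoma and for measuring how accurately a
plan was executed.  The anatomy is carried as triangle meshes in a
right-handed world frame in millimetres; volumes map voxel index
`(i, j, k)` to world coordinates as `origin + spacing · (i, j, k)` (0-based).
Rigid motions are proper rotations plus translations (`det R = +1`, enforced
to 1e-9); mirror images are a distinct reflection type derived from a plane,
so the rigid-group invariants stay checkable.  All randomness anywhere in the
package flows from explicit integer seeds; a pipeline run is a pure function
of its inputs, config and one global seed (fanned out per stage by a CRC of
the stage name).

## Segmentation

Bone is segmented from a CT-like volume by thresholding (default 300 HU, the
conventional cortical-bone cutoff) followed by 26-connected component
selection at user seeds — the union over seeds, so adding a seed can only
grow the mask and re-running a mask's recorded provenance reproduces it.
Surfaces come from marching cubes at the 0.5 iso-level of the zero-padded
binary mask, computed in index space and scaled afterwards, so anisotropic
voxels are handled exactly.  No morphological smoothing is applied by
default (an optional binary-closing radius exists): the geometry pipeline
stays deterministic and auditable.

## Symmetry plane and registration

The midsagittal plane is fitted from landmarks rather than detected from the
surface: with ≥ 2 bilateral pairs the plane passes through the centroid of
the pair midpoints with its normal along the mean left→right direction (the
least-squares perpendicular-bisector plane); with ≥ 3 midline landmarks a
total-least-squares plane is used instead.  Pairs belonging to the displaced
segment are excluded — they are asymmetric by definition and measurably bias
the plane.

Alignment of the displaced segment onto the mirrored template is two-stage:

* **Landmark stage** — Kabsch/Umeyama without scaling on ordered point
  pairs; the SVD's reflection branch is rejected, collinear or duplicate
  configurations raise.
* **ICP stage** — trimmed iterative closest point with exact
  nearest-point-on-triangle correspondences (never nearest-vertex, which
  biases coarse meshes).  The update step is a linearized point-to-plane
  solve, re-orthonormalized through the Rodrigues map; point-to-point ICP
  slides tangentially so slowly on smooth anatomy that it is kept only as an
  alternative (`method="point_to_point"`).  Each iteration drops the worst
  `trim_fraction` (default 0.1) of correspondences, protecting against
  fracture edges with no counterpart.  A step that increases the trimmed RMS
  is rejected, so the reported RMS is non-increasing; iteration stops at
  `tol_mm` improvement (default 1e-4) or `max_iter` (default 100).  Sources
  are subsampled to ≤ 5000 area-uniform points, seed-controlled.

The registration source is always the segment's **outer bone surface**: the
cross-sections left by a virtual osteotomy exist on no CT-derived template,
and keeping them measurably degrades the fit (~2° / 2 mm on phantoms).

A caveat established during validation: for surface noise of σ = 0.2 mm the
nearest-distance objective is nearly flat along directions tangential to a
smooth malar patch, so the *optimum itself* wanders 0.3–0.7 mm from ground
truth.  Surface matching alone cannot beat that; the tests assert the
measured 5σ bound rather than a hoped-for sub-noise accuracy.  Noiseless
recovery is exact to ~1e-2° / 1e-2 mm.

## Reverse-sequence planning

Drill holes are planned on the *repositioned* anatomy first and only then
transported back, which is what makes the fixation plate double as a
repositioning guide:

1. `cut_segment` splits the closed pre-op mesh by the osteotomy planes
   (anterior / posterior labels; the posterior cut is flagged
   access-limited).  Cutting is plane slicing with ear-clipped cross-section
   caps, so both outputs stay closed and volumes are conserved exactly at
   zero kerf; a nonzero kerf removes the saw-blade slab.  If the planes also
   shave slivers elsewhere, a hint point selects the intended body.
2. `place_drill_holes` snaps each requested hole to the nearest surface
   point of the mesh matching its role (moving / stable); the drill axis is
   the inward surface normal; requests > 5 mm off-surface and holes closer
   than 1.5× diameter are rejected.
3. `backward_transpose` maps moving holes through the inverse alignment
   (positions and axes); stable holes copy unchanged; frames are tagged and
   mixed-frame inputs rejected.
4. `build_guides` seats an offset shell (default 2 mm thick, 8 mm footprint
   radius) on the pre-op surface around each proximity-grouped hole cluster,
   with a through-cylinder per hole and a kerf-wide slot per osteotomy plane
   crossing the footprint.  A hole that was not backward-transposed is off
   the pre-op surface and raises — the error the reverse sequence exists to
   prevent.  Patch vertices where two boundary loops touch (bowties) are
   excised so every guide component is a closed manifold.
5. `verify_plan` checks the contract: alignment(pre-op hole) must land on
   its planned counterpart (machine precision by construction), stable holes
   identical in both frames.

PSI plates are represented by their hole pattern plus a surface-footprint
shell; freeform plate sculpting is out of scope.  Guide dimensions are
configurable; no published dimensions exist for them.

## Distance analysis

Cloud-to-mesh distances use an exact point-to-triangle kernel (region-based
clamping) under a KD-tree culling scheme: triangles are bucketed into
geometric size classes by bounding radius, each class's centroid tree is
queried at `d_nearest_vertex + max_radius(class)`, and all candidates are
evaluated with the same kernel as an exhaustive scan.  Minima are therefore
**bitwise identical** to the O(N·M) brute force — dot products are written
as explicit column arithmetic because `einsum` reductions round differently
across batch shapes.  Signs use the nearest triangle's normal, with an
angle-averaged pseudonormal at edge/vertex ties; positive means outward
projection (rendered orange in heat maps, negative/inward blue, saturating
at the 95th percentile by default).

Summary statistics: mean of absolute distances (the headline number), RMS,
directed Hausdorff maximum, 50/90/95th percentiles, and a histogram over
*signed* distances with 0.25 mm default bins (counts conserve the sample
count exactly).  Mesh-vs-mesh comparisons sample the test surface at
10 points/mm², seed-controlled.

`extract_outer_shell` removes interior walls (sinus linings, canals) before
comparison: orthographic ray grids are cast along Fibonacci-distributed
directions (default 32) at half the median edge length, and only first-hit
faces are kept — a z-buffer formulation, so cost scales with surface area,
not rays × triangles.

Soft-tissue comparison reuses the same machinery on offset envelope
surfaces, optionally restricted to a spherical malar region of interest,
with an optional trimmed-ICP pre-alignment (trim 0.4) for scanner data that
shares no CT frame.

## Synthetic cases (what the phantom does and does not emulate)

The phantom is parametric-analytic: an ellipsoidal cranium (semi-axes
40 × 50 × 45 mm — roughly half adult scale, chosen once to keep desk-scale
runtimes; all error metrics remain in clinical units) carrying two
mirror-symmetric zygoma-like prominences, built by marching cubes over an
implicit union on a grid symmetric about x = 0 (the left bump evaluates the
right bump's implicit at the reflected point, so symmetry is exact to
floating point).  The prominence is a triaxial ellipsoid (14 × 10.5 ×
7.7 mm): a spherical bump would leave rotation about its own axis
unidentifiable for any surface registration.  Landmarks (bilateral stable
pairs, midline points, four segment points) are defined analytically, hence
symmetric to machine precision.

The malunion cuts the right prominence free with an anterior/posterior plane
pair (±12° tilt) and displaces it by a configurable rigid transform; the
default, 5 mm medial + 2 mm posterior with 8° rotation about the vertical
axis through the segment centroid, reproduces the typical depressed,
medially impacted malar.  Penetration of the displaced segment into the
skull is measured by signed distance and rejected beyond 8 mm (the default
malunion itself impacts by ~5 mm, which is the clinical picture, not an
error).  Gaussian vertex jitter (σ configurable) models CT surface noise —
coherent per vertex, not per sample.

Rasterization uses z-column ray parity with an irrational sub-voxel origin
jitter; closed bodies are voxelized separately and unioned (parity over a
concatenation of overlapping solids would carve a cavity in the overlap),
and columns whose crossing count is odd or contains near-duplicate heights —
the signatures of a ray grazing a triangle seam — are re-cast at a tiny
deterministic lateral offset.  A 20 mm sphere at 0.5 mm spacing recovers its
analytic volume to < 2%.

What the phantom does **not** emulate: real CT physics (partial volume, beam
hardening, metal artifacts), fracture comminution or missing bone, thin
pneumatized walls, biological remodeling of fracture lines, and soft-tissue
mechanics (the envelope is a constant-thickness offset).  Passing phantom
tests therefore demonstrates the *geometric* correctness and noise behaviour
of the chain, not segmentation robustness on clinical scans.

## Validation experiments and problem sizes

The experiments module (shared by the test suite and
`scripts/acceptance.py`) runs, per invocation: noiseless malunion recovery;
zero-noise closure through the mesh route and through a synthetic post-op CT
(0.5 mm voxels, ~200³ volume, ~300 k-face reconstruction); a 20-seed study
at σ = 0.2 mm vertex noise + 0.5 mm voxels whose median planned-vs-post-op
mean distance stays well below 0.75 mm (measured ≈ 0.066 mm — pure
voxelization error, since the comparison is invariant to the shared
alignment); a 100-pair bitwise oracle comparison; and the one-vs-two-plate
simulation (150 noise draws, 4 holes per layout, plate footprint 6 mm,
cluster separation ≈ 19 mm), where two separated plates reduce the median
segment-orientation error to ≈ 60–65% of a single plate's.

## Known limitations

* Cap triangulation assumes the plane cross-section is a set of simple
  polygons (true for the anatomy-like shapes here); nested cross-section
  loops (an annulus) would be capped without the hole.
* `soft_tissue_surface` removes locally flipped faces after offsetting but
  does not resolve global self-intersections in deep concavities.
* The symmetry plane requires landmarks; automatic symmetry detection is out
  of scope.
* Guide meshes are closed component assemblies (shell + cylinders + slots),
  not a single boolean-merged solid — adequate for geometry checks and for
  downstream CAD, but not directly printable without a boolean union.
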