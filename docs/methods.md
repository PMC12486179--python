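# Methods

This note records the models, conventions and numerical choices behind
`cysthead`, in the order the pipeline runs them.

## Grid and coordinate contract

All images are regular voxel grids with per-axis spacing (mm) and an
origin at the centre of voxel (0,0,0); world position = origin + index ×
spacing (voxel-centre convention).  Axes are (x, y, z) = (mediolateral,
anteroposterior, superoinferior).  Masks and label maps always carry the
grid of their parent volume; any grid mismatch downstream raises — the
pipeline never resamples silently.  NIfTI is the default on-disk format;
TIFF stacks (ImageJ spacing metadata, or explicit `spacing=`) and
MetaImage are also read and written.

## Cyst extraction

1. **Binarization.**  Bone = intensities in the fixed window 90–255,
   both ends inclusive (so a voxel at exactly 90 is bone).
2. **Total region.**  Morphological closing with a 1.5 mm ball followed
   by 3D hole filling; the result is forced to contain every bone voxel.
   The closing radius only needs to exceed the largest surface pore and
   is configurable.
3. **Empty regions.**  Set difference total \ bone.  Bone voxels outside
   the total region (possible only on malformed inputs) are logged and
   clipped, preserving the partition law bone ∪ empty = total,
   bone ∩ empty = ∅.
4. **Size filter.**  "More than 1 mm in diameter" is interpreted as the
   largest-inscribed-sphere diameter.  The filter is an opening by
   reconstruction: erosion by a discrete ball of radius
   `min_diameter/2`, applied as `k = min_diameter/(2·step)` increments of
   `step` (defaults 1.0 mm and 0.5 mm, so one increment), then geodesic
   reconstruction of the survivors inside the original empty mask.  For
   binary masks, reconstruction run to idempotence is exactly "keep every
   connected component containing an erosion survivor, in full", which is
   how it is computed.  Consequences: components are retained iff their
   largest inscribed (discrete) sphere reaches the threshold radius;
   retained components come back voxel-identical to their original
   extent (a dumbbell whose neck is far below 1 mm survives as one
   component, neck included); the filter is idempotent.  The ball is
   discretized on the voxel grid (offsets whose physical distance is at
   most the radius, per-axis extents rounded to the nearest voxel), so
   the effective threshold is the discrete-ball radius; the unit suite
   pins this against a brute-force ball-fit oracle exactly.
5. **Labelling.**  Foreground connectivity 26, background 6 (the
   standard complementary pair).  Components 6-adjacent to the exterior
   of the total region — including the region beyond the array bounds —
   are flagged `touches_exterior` and excluded from the records by
   default: they are surface defects (collapse, resection margins), not
   interior cysts.  `include_surface_voids=True` keeps them.  Per cyst:
   volume = voxel count × voxel volume; maximum inscribed diameter =
   2 × peak Euclidean distance-to-surface; centroid in world mm.
6. **Summary.**  Cyst.N, Cyst.V, CystV.Ave/Min/Max; an empty record set
   reports N = 0, V = 0 and null Ave/Min/Max.
7. **Mineralization map.**  Bone voxels classed low/intermediate/high by
   the intensity tertiles computed within the bone mask; ties go to the
   lower class; constant-intensity bone degenerates to all-intermediate
   with a warning.

The analysis is fully 3D.  Slice-wise 2D analysis of coronal sections
can be emulated by passing single-slice volumes, but the 3D route is the
primary, tested path.

## Six-region segmentation

The reference plane passes through the head, fovea and neck/calcar
centres.  Its normal is oriented toward the anterior side from the
`side` field: with n₀ = normalize((fovea − head) × (neck − head)), the
anterior normal is +n₀ for a left hip and −n₀ for a right hip.  The
width axis w = normalize(n × MTD) lies in the reference plane and is
perpendicular to the MTD; the cutting planes are true world-space planes
normal to w.

Head width is the extent of the head mask's voxel footprints projected
on w — the centre extent plus one voxel footprint (½·Σ|wᵢ|·spacingᵢ per
end) — so a digitized sphere of radius R measures 2R rather than 2R
minus a voxel.  Cuts sit at the cumulative 30 % and 70 % width
quantiles (width-quantile placement rather than symmetric offsets from
the head centre, matching the width-percentage definition of the
pillars).  The lateral pillar is the w end farther from the fovea, which
is anatomically medial — no hidden handedness parameter; a fovea
projecting exactly onto the head-centre width coordinate is an error.
Voxels are classified by the signed distance of their centres; the
hemisphere rule is anterior ⟺ signed distance ≥ 0.  Regions: I–III =
anterior lateral/central/medial, IV–VI = posterior.

Cyst region assignment follows the distribution-area rule: the region
holding the largest overlap fraction of the cyst wins; exact ties go to
the lower region index and are flagged; the full six-way overlap vector
is kept in the record.

When no MTD is supplied, `estimate_mtd` uses the principal (longest)
axis of the mean-intercept-length fabric tensor of the bone mask — a
stand-in for manual placement, clearly labelled as such.  Near-isotropic
structure (MIL axis ratio < 1.05) falls back to the superoinferior axis
with a warning.

## Trabecular morphometry

All parameters are computed on bone within an ROI; the Cys-Tb ROI is
dilate(cyst, ball 0.5 mm) \ cyst, clipped to the total region, and is
disjoint from the cyst by construction.  A shell width below one voxel
is rejected with a pointer to the voxel size.

* **BV/TV** — voxel counting, exact.
* **Surface (BS, BS/BV)** — marching cubes at the 0.5 level of the
  one-voxel-sigma Gaussian-smoothed binary mask.  Smoothing removes most
  of the staircase area bias of a raw binary isosurface (a digital
  sphere of radius 20 voxels measures within ~0.5 % of 4πr²; raw
  marching cubes is ~9 % high).  For ROI-style analysis the mask is not
  zero-padded, so structure crossing the ROI border is treated as
  continuing (open surfaces).
* **Tb.Th / Tb.Sp** — sphere-fitting local thickness (distance ridge):
  per voxel, the diameter of the largest inscribed sphere containing it,
  computed by stamping spheres in descending exact-radius order;
  the map equals the brute-force all-pairs definition exactly, and only
  the voxels the ROI needs are filled (centres farther than the global
  maximum radius cannot contribute).  Radii come from the Euclidean
  distance transform to the nearest background voxel centre; the value
  is the volume-weighted mean over mask ∩ ROI, in μm.  Tb.Sp is the
  same measure on the void phase (complement of bone, clipped to the
  total region).
* **Tb.N** — 1/(Tb.Th + Tb.Sp), the model-free hybrid definition, chosen
  because the parameter name alone does not fix a formula; it is exact
  for parallel plates and scale-covariant.
* **SMI** — 6·V·S′/S² with S′ estimated by dilating the triangulated
  isosurface: every vertex moves half a voxel along its outward normal
  and the triangle areas are re-summed.  Ideal plates/cylinders/spheres
  give ≈0/3/4 at ≥12 voxels across the minor dimension; concave
  structures can legitimately go negative, as is well known for this
  index.
* **DA** — mean intercept length over ≥512 quasi-uniform (Fibonacci
  hemisphere) directions, 128 random test lines per direction marched at
  half-voxel steps; MIL(ω) = bone length per bone-entry intercept.  An
  ellipsoid 1/MIL² = ω·A·ω is least-squares fitted; DA = longest /
  shortest principal MIL (≥ 1); the CTAn-style 1 − min/max convention is
  available via `da_convention`.  Fewer than 100 total intercepts logs a
  stability warning.
* **Conn.D** — (1 − χ)/TV with χ the Euler characteristic of bone ∩ ROI
  under foreground-26 connectivity, computed on the zero-padded mask (no
  mirror boundary).  The unit suite pins χ against an independent
  cubical-complex V − E + F − C counting oracle.

## Histomorphometry (2D)

The module consumes already-labelled sections (0 marrow, 1 mineralized
bone, 2 osteoid, 3 eroded-surface marker); colour segmentation of
stained slides is out of scope.  The bone surface BS is the 4-adjacency
boundary between solid (classes 1–3) and marrow, with out-of-image
neighbours counting as marrow.  OV/BV = osteoid area over total solid
area; OS/BS and ES/BS are the boundary-length fractions whose solid
pixel is osteoid or eroded-marked; OS/BV, ES/BV and ES/TV are boundary
length per solid area and per section area.  Length densities are
reported as raw 2D mm/mm² by default; `stereology=True` applies the
standard 4/π section-to-volume correction, after which the units read
mm²/mm³ (both conventions are emitted because reporting practice is
inconsistent on this point).  O.Th is the mean 2D inscribed-disc
thickness of the osteoid seams.  Microvessel density follows the
Weidner rule: per field, connected components at 8-connectivity (so
touching endothelial clusters count once); per-field counts and their
mean across the (default ten) fields are both reported.

## Group statistics

Continuous variables: a Lilliefors-corrected one-sample KS normality
test (parameters estimated from the sample; the uncorrected KS of
legacy software is available via `method="ks"`) routes at α = 0.05 to a
pooled-variance independent t-test when both groups pass, otherwise to
a two-sided Mann–Whitney U (normal approximation, tie correction).
Welch's t is behind a flag.  Samples too small or degenerate for the
pre-test (n < 4 or constant) route to Mann–Whitney.

Categorical variables default to the uncorrected Pearson chi-squared:
on the published baseline table this is the only member of the
chi-squared family that reproduces all four printed 2×2 p-values
(0.903, 0.908, 0.292, 0.425) to three decimals, so it is the default
"as applicable" rule; Yates-corrected chi-squared and Fisher's exact
test are available explicitly, and Fisher is auto-selected when any
expected count falls below 1.  The printed hypertension row (0.724) is
not reproduced by any uncorrected variant (chi-squared gives 0.707) and
is documented as non-reproducible rather than targeted.  Summaries are
mean (SD) for continuous and n (%) for categorical data; significance
is two-tailed at 0.05; missing values are deleted pairwise with
per-variable n reported.  No multiple-testing correction is applied, by
design.

## Synthetic phantoms

The head phantom emulates a specimen micro-CT scan: a spherical head of
trabecular bone with a cortical shell and carved cysts, at a default
voxel size of 0.0736 mm (tests use 0.15–0.25 mm for speed).

* **Texture.**  A Gaussian random field with autocorrelation length
  `strut_scale` (default 0.25 mm), stretched along the MTD (z) by
  `anisotropy_stretch`, thresholded at the quantile hitting
  `bone_fraction_target` (default 0.30) inside the trabecular
  compartment.  A raw thresholded field has a heavy pore-size tail that
  real femoral-head trabecular spacing does not; pores are therefore
  capped at `max_pore_diameter` (default 0.7 mm, safely below the 1 mm
  cyst rule) by patching the cores of oversized pockets with bone.  The
  patching can leave small detached bone islands; phantom connectivity
  is therefore not anatomically meaningful and the morphometry analytic
  suite uses ideal solids for Conn.D instead.
* **Cysts.**  Spheres carved as voids and sealed by a sclerotic bone rim
  (default 0.3 mm, floored at two voxels so the discrete shell is
  watertight); real cyst rims are often discontinuous, but a sealed rim
  is what makes a carved void an *interior* cyst in the sense of the
  detection pipeline.  Overlapping cysts (rims included) and cysts
  reaching outside the trabecular compartment are rejected with the
  offending indices.
* **Intensities.**  Marrow ≈ 40, bone ≈ 160 (air 0), so the 90–255
  window separates the classes before noise; Gaussian blur (default
  0.05 mm) stands in for partial-volume effects and additive Gaussian
  noise (default SD 8) for detector noise — at 8 SD the 120-unit class
  gap makes threshold misclassification negligible, which is the regime
  a well-calibrated specimen scan operates in.  Contrast values are
  conventions, not calibrated to any scanner.
* **Ground truth.**  Per-cyst label volume, analytic and voxel-count
  volumes, the truth bone mask, the head mask and the landmark set
  (head centre at the origin, fovea on the medial +x surface, neck
  centre inferior, MTD = z, left hip).
* **Shell presets.**  `SCLEROTIC_SHELL` (bone fraction 0.40, strut scale
  0.30 mm, stretch 1.1) and `LYTIC_SHELL` (0.15, 0.30 mm, 1.8) encode
  the degenerative-versus-necrotic peri-cyst contrast: same
  architectural scale, but dense/near-isotropic versus
  thinned/wide-spaced/aligned.  On these, all eight panel parameters
  order as reported for the two diseases (BV/TV, Tb.Th, Tb.N, Conn.D
  higher in the sclerotic condition; BS/BV, Tb.Sp, SMI, DA lower).
* **Histology sections** are 2D analogues: GRF bone texture, osteoid
  laid down as surface seams (shallowest bone pixels first) to an exact
  pixel-count quota, eroded markers on boundary pixels to an edge-count
  quota; realized fractions are recorded as ground truth.
* **Cohorts** draw named continuous (normal / lognormal / uniform) and
  binary variables per group from a seeded generator.

Everything is bit-reproducible for a fixed seed.

What passing on phantoms does *not* show: the generator has no
fibrous cyst content, no subchondral fracture or collapse geometry, no
intensity calibration (BMD), no cartilage, and GRF texture is blobbier
than real trabecular architecture — so phantom results validate the
*operations*, not clinical performance on real specimens.

## Problem sizes and tolerances

The test suite runs phantoms at 0.15–0.25 mm voxels and heads of
8–16 mm radius (the defaults a scientist would scale up for production
runs at 0.0736 mm).  Key tolerances: detection volumes ±10 % of the
analytic sphere at ≥8 voxels per diameter; local thickness ±1 voxel on
analytic solids (with cylinder axes on voxel centres — off-centre
placement costs up to another half voxel of digitization bias); surface
areas ±5 %; SMI ±0.3 on ideal solids at ≥12 voxels across; DA within
[1, 1.15] on isotropic fields with 512 directions; pillar widths within
one voxel layer of 30/40/30.  Euler characteristics, BV/TV, the size
filter and the thickness map are checked exactly against independent
oracles.

## Known limitations

* SMI inherits the known concavity bias of the surface-dilation
  definition; values on dense plate-like bone can be negative.
* The MIL estimator samples randomly; DA fluctuates by a few percent
  across seeds (the seed is plumbed through every API).
* The MTD estimator is a stand-in for manual landmarking and degrades on
  near-isotropic heads (it then falls back to the z axis).
* 2D surface densities depend on the stereology convention; both raw and
  corrected values are available but must not be mixed across studies.
* Exterior-touching voids are excluded automatically, which stands in
  for, but is not identical to, expert exclusion of collapse defects.
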