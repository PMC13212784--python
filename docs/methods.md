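# Methods

This note documents the models, numerical choices and limitations behind
`nwuct`. It is written for users who need to judge what the pipeline
computes, why the defaults are what they are, and what the synthetic test
bed does and does not demonstrate.

## The NWU model

Net water uptake treats early ischemic edema as a proportional density
deficit: if healthy tissue at a location attenuates with mean `HU(B)` and
its infarcted mirror image with mean `HU(A)`, the percentage of took-up
water is `NWU = (1 − HU(A)/HU(B)) × 100`. The model assumes (a) the two
hemispheres are attenuation-symmetric in health, (b) the deficit is driven
by edema rather than by chronic lesions, hemorrhage or beam-hardening, and
(c) regions A and B contain comparable tissue composition. The pipeline
operationalizes (a) and (c) geometrically — template alignment, mirroring,
deformable correspondence, parenchyma-band masking — and leaves (b) to the
user's case selection.

## Pipeline stages and parameters

**Resampling.** Everything is computed on a 1 mm isotropic grid
(`target_spacing`). Output grids are chosen so no sample point falls outside
the input domain; linear interpolation for HU, nearest-neighbour for masks.

**Template alignment.** The moving NCCT is registered to a left–right
symmetric template so the midsagittal plane becomes the central sagittal
slice. Because no distributable CT atlas exists, the default template is the
package's own noise-free symmetric phantom; users with a proper symmetric
atlas can pass it instead. Registration is multi-resolution (3 levels,
shrink 4/2/1) Mattes mutual information (32 bins, 5% random sampling,
seeded) with a regular-step gradient descent. It runs in two stages: a
rigid (Euler) stage followed by affine refinement initialized from it. A
single-stage affine search proved unreliable on head-like shapes — the
near-ellipsoidal skull lets the optimizer trade rotation against shear and
stall a few millimetres off — while rigid-first recovers 10°/10 mm motions
to well under 0.1 mm. The rigid stage is additionally multi-started over
`affine_restarts = 3` deterministic sampling seeds and keeps the candidate
with the best full-image metric; occasional sampling draws otherwise leave
the optimizer in a recognizably poor optimum. If optimization ever worsens
the metric relative to the centred initialization, the initialization is
kept.

**Hemisphere split and mirroring.** The aligned volume splits at the
central sagittal plane; the right half is flipped onto the left half's
frame. For an odd-sized split axis the central slice joins neither
hemisphere, so midline structures are never counted twice. Mirroring is an
exact involution.

**Deformable hemisphere registration.** Residual anatomical asymmetry is
absorbed by symmetric-forces demons registration of the mirrored hemisphere
onto the other: two scales (shrink 2, then full resolution; 40/20
iterations), Gaussian field regularization with sigma = 2 mm, displacement
magnitudes capped at 10 mm. The contract enforced in code is normative
rather than algorithmic: the warp must not increase the mean squared HU
difference on interior soft tissue (HU in (0, 100), eroded 3 voxels — at
bone and air interfaces a sub-voxel shift already changes HU by tens of
units and would swamp the parenchymal signal), and the field must have a
positive mean Jacobian determinant. If the improvement contract fails the
identity field is used and flagged in the diagnostics. Synthetic smooth
deformations up to 4 mm are recovered with mean endpoint error around
0.4 mm.

**Contralateral sampling for intensity means.** The deformation field is
used to pair pooled windows for the NWU map only. The *reported* total NWU
(and the reference-mask NWU in benchmarking) samples the mirrored
contralateral region of the original aligned image, restricted to the
parenchyma HU band. The reason is a pathology-registration effect observed
during development: an intensity-driven registration partially "heals" the
hypodense lesion in the warped hemisphere (and fabricates a faint pseudo
lesion on the other side), because warping healthy tissue to match the
lesion is exactly what minimizes its objective. That bias reached several
percentage points of NWU for large lesions. Mirrored-ROI sampling is the
standard clinical definition of the contralateral region and is unbiased in
the aligned symmetric frame.

**Parenchyma mask.** Per hemisphere: HU > 0, then the open band
(`csf_hu` = 14, `bone_hu` = 60) removing CSF and bone, then exclusion of
voxels whose 3D Sobel gradient magnitude exceeds `edge_threshold` = 120
HU/voxel (skull margins and partial-volume interfaces). The HU band follows
common parenchyma windows; the band and the edge threshold are
config-exposed because neither is canonical. Per-rule exclusion counts are
logged for interpretability.

**Masked average pooling.** An 11×11×11 mm kernel (11³ = 1331 voxels at
1 mm) slides over each hemisphere; each voxel receives the mean HU of
in-mask voxels in its window. Windows with fewer than
`floor(0.10 × 1331) = 133` in-mask voxels are invalid; the count is always
taken against the full nominal kernel volume, also at volume borders.
Implementation uses separable moving sums (scipy `uniform_filter`) and
matches a brute-force sliding-window oracle to 1e-6.

**NWU map.** The pooled fields of the two hemispheres are combined per the
NWU formula, in both sign conventions (each hemisphere once as A). Validity
requires both windows valid and a positive denominator; values are clipped
to [−30, 30]% to suppress pathological ratios at mask boundaries.

**Lesion extraction.** One Otsu threshold is computed over the pooled
positive NWU values of both conventions (256 bins over the observed range,
threshold at the bin edge maximizing between-class variance; ties across an
empty histogram gap resolve to the plateau midpoint, Otsu's original rule).
The working threshold is `max(otsu, lower_cutoff)` with
`lower_cutoff` = 2.5% guarding lesion-free maps whose histogram is pure
background noise. The affected side is the convention with the larger
supra-threshold volume. The candidate mask is reduced to its largest
connected component (26-connectivity; size ties resolve to the component
with the smallest linear voxel index), then refined by erosion and dilation
with equal ball radii (2 voxels each) and interior cavity fill, and reduced
to one component again. Equal radii — a volume-preserving opening — are
deliberate: a net-dilating refinement systematically admits healthy tissue
into the mask and dilutes the NWU estimate toward zero. Masks below 1 mL
are reported as "no lesion", mirroring the usual exclusion of sub-mL
lesions.

**Evaluation.** Dice, any-voxel detection, axis-aligned bounding-box IoU
with the detection threshold 0.5^(3/2) ≈ 0.354 (the 2D half-overlap
convention extended to 3D; the comparison is strict `>`), and NWU error
statistics (MAE, ME, median AE, IQR, SDs). With one detection per case and
no confidence ranking, mAP reduces to the fraction of cases whose box IoU
exceeds the threshold. Two empty masks count as perfect agreement
(Dice = 1, detected, IoU = 1). The reference NWU is computed from the
reference mask with the same mirrored-ROI machinery as the computed NWU, so
both share the image and alignment.

## The synthetic phantom

A phantom is an ellipsoidal head on a 110×140×90 grid at 1 mm: a 4 mm
skull shell at 1200 HU, a 2 mm CSF margin at 8 HU, parenchyma at 35 HU
modulated by a smooth, bilaterally symmetric multiplicative texture (±5%,
12 mm correlation length — a stand-in for gray/white contrast that keeps
pooling and Otsu non-degenerate), paired ventricles at 8 HU, and optionally
one ellipsoidal lesion (shape ratios 0.75 : 1.15 : 1 in the
left-right / antero-posterior / axial directions). The lesion multiplies
the underlying tissue by `(1 − w/100)`; because the pre-lesion image is
exactly mirror-symmetric, the ground-truth NWU of the lesion mask is
exactly `w`. The lesion boundary is sharp by default; an optional Gaussian
edge blur emulates subtle hypoattenuation but breaks the exactness of the
ground truth and is therefore off by default. Additive Gaussian HU noise
and a smooth random one-sided deformation ("asymmetry") can be layered on;
both are seeded and the whole construction is bitwise deterministic per
seed.

The default suite (20 cases) crosses uptakes {5, 10, 15, 20}% with lesion
volumes swept over 10–60 mL, cycles noise sigma over {0, 1, 2, 3, 4} HU and
alternates sides; lesion centres are sampled with a containment check
against the brain boundary (ventricle overlap is tolerated — the realized
ground-truth mask excludes CSF by construction, so it only trims the
realized volume slightly below the request). These conditions are meant as
a strictly easier analogue of early-stroke NCCT: real scans add skull-base
artifacts, gantry tilt, chronic lesions, asymmetric ventricles and far
richer texture. Passing on phantoms therefore demonstrates correctness of
the machinery and graceful degradation with noise — not clinical
performance.

## Numerical choices and degenerate inputs

- HU volumes are float32 in memory; pooling and statistics run in float64.
- Pooled counts come from a separable uniform filter and are rounded to
  integers; values at zero-count voxels are NaN and never valid.
- Otsu requires at least two distinct values; a constant sample raises a
  degenerate-histogram error, which the pipeline treats as "nothing above
  noise" (the lower cutoff then decides, typically yielding no lesion).
- An empty lesion mask is a valid outcome, not an error; side is then
  "none" and the total NWU is null.
- The single global seed fans out to stage-specific seeds (hashed), so
  stages are decoupled but the whole run is deterministic; run reports
  embed the configuration and its content hash.

## Problem sizes

Unit tests run on miniature heads (64×80×56) with a proportionally smaller
7 mm pooling kernel, so a ~4 mL lesion stays resolvable relative to the
kernel; pipeline-level checks and the acceptance script use the full
110×140×90 phantom with the default 11 mm kernel and the 20-case suite
described above.

## Known limitations

- The default template is the package's own phantom; aligning clinical
  NCCT to it is geometrically meaningful (symmetry, midplane) but not
  anatomically standardized (no true AC-PC landmarks).
- Direction cosines are carried through I/O but the hemisphere split
  assumes the canonical RAS frame produced at load; strongly oblique
  acquisitions rely on the template alignment to correct orientation.
- One lesion per case: multi-focal infarcts collapse to the largest
  supra-threshold component.
- No core/penumbra differentiation, DICOM ingestion, HU calibration or
  gantry-tilt correction.
- Demons correspondence is intensity-driven; it is deliberately kept away
  from the reported intensity means (see above) but still shapes the NWU
  map near strong asymmetries.
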