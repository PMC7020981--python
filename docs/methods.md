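# Methods

`dixonct` generates a synthetic CT for abdominal radiotherapy planning
from a single mDixon MR acquisition (co-registered in-phase, fat-only
and water-only volumes) by classifying every voxel into five tissue
classes — air, lungs, fat, high-density tissue, spine — and assigning
each class a population-based Hounsfield unit. This note records the
model, the parameters that matter, the numerical choices, and what the
bundled digital phantom does and does not establish.

## Canonical frame and grids

Volumes are held with array index order `(x, y, z)` and axes pointing
left / posterior / superior (LPS); `z` is the slice axis. Everything
metric (morphological radii, region-growing distances, surface
distances, margins) is computed in physical mm via the voxel spacing,
so the rules behave identically on anisotropic grids. Inputs are
reoriented to this frame on read; the three channels must agree in
shape, spacing (1e-4 mm), origin and orientation (`check_cohort`).

## Preprocessing

**Bias field (N4).** Each channel is corrected independently with N4,
estimated only inside the body (different receive-coil weightings per
channel justify per-channel fields). Defaults: cubic B-spline, one mesh
element per axis, shrink factor 4, three levels with 50/40/30
iterations, convergence 1e-4. Two practical guards: intensities are
clipped to ≥ 0.01 before the log transform (magnitude MR noise floors
cross zero), and a (near-)constant volume (within-body CV < 1e-3)
returns a unit field — bias estimation is ill-posed there and N4's
histogram deconvolution degenerates. Because the body is needed before
the first correction, a provisional Otsu body mask from the raw
in-phase image supports N4; the definitive mask and threshold are
recomputed afterwards on the corrected, denoised in-phase volume.
Residual limitation: on strongly textured anatomy N4 absorbs some
tissue contrast into the field; on the phantom the recovered field
correlates >0.99 with the truth on a smooth volume but ~0.95 on the
textured channel. The pipeline is insensitive to this because all
later thresholds are data-derived.

**Difference image.** dMRI = fat − water. Inside the body its histogram
has three modes: water-dominant soft tissue (strongly negative), the
low-signal mixture of air/lungs/bone (near zero), and fat (strongly
positive). This is the single feature the clustering uses.

**Denoising.** A conservative explicit Perona–Malik diffusion
(diffusivity `exp(-(g/kappa)^2)`, Neumann boundaries) is applied to all
four volumes. `kappa = 2.0 ×` the within-body interquartile range, 5
iterations, step 0.0625 (stability bound 1/6 on a 3D grid). The scheme
conserves the global mean exactly and obeys the maximum principle;
parameters are deliberately mild so the three histogram modes survive.

**Body mask.** Otsu threshold on a 256-bin whole-volume histogram;
largest above-threshold 3D component; closing with a 5 mm ball
(erosion run with border value 1 so a body touching the first/last
slice is not shaved); full-3D hole filling so lungs and bowel gas lie
inside the body. The threshold is reused for low-intensity extraction.
Note for piecewise-constant (noise-free synthetic) data the Otsu
criterion can be flat between modes and the returned threshold sits at
a plateau edge; with any realistic noise the optimum is unique.

## Spatially constrained fuzzy c-means

Classic FCM (fuzzifier m = 2) on the body voxels of dMRI, three
clusters, centroids initialized at the 10/50/90th within-body
percentiles — deterministic by construction. The spatial constraint is
a membership-smoothing post-step each iteration:
`u' = (1−λ)·u + λ·mean(u over the 3×3×3 neighborhood, body voxels
only)`, then renormalization; λ = 0.3. With λ = 0 the scheme is exact
alternating optimization (objective monotonically non-increasing — a
property the tests check, and a small-instance grid-search oracle
confirms the fixed point). Convergence: max membership change < 1e-4 or
200 iterations (warning, result still returned). Cluster identity is
assigned from the sorted centroids: lowest → high-density tissue,
middle → mixed low-signal, highest → fat; ties raise.

## Rule-based localization of the mixed cluster

*Lungs.* Low-intensity voxels (in-phase below the Otsu threshold,
inside the body) are filtered per axial slice: 2D components with area
strictly below 3500 voxels (a raw count at the reference in-plane
resolution, configurable) are removed — bowel gas and bone fall below,
lung cross-sections above. Survivors select their 3D connected
components within the low mask (the fixed point of seeded growth over
the low-intensity band), then 2 mm closing and hole filling.

*Air.* The residual low mask is eroded by 2 mm — this erases thin
cortical-bone shells — and survivors are grown back within the
residual to reconstitute whole pockets; opening and removal of
components < 50 voxels clean up. Residual voxels not claimed are kept
as solid-bone candidates.

*Spine.* A per-slice prior box: the posterior 12–45 % band of the
body bounding box intersected with the central 30 % of the left-right
extent. (a) The prior minus air/lungs/fat is restricted to fat-bright
voxels (Otsu split of the fat-channel intensities inside the candidate
mask, applied only when the bright/dark means separate by >1.5×) —
bone marrow is fat-bright while the muscle and organs sharing the box
are fat-dark — then opened in 2D (3 mm), keeping components near the
prior's center column. (b) Per-slice region growing from marrow and
from bone candidates inside the prior accepts voxels whose fat-channel
intensity lies within ±50 % of the seed median and within 15 mm of a
seed. (c) The spinal cord is removed as the per-slice circular
(4π·area/perimeter² ≥ 0.6) low-fat component of radius ≤ 8 mm posterior
to the vertebral-body centroid. (d) Largest 3D component, hole-filled,
re-restricted so air/lung/fat voxels are never claimed. Ribs are
deliberately not segmented and end up as a fat/high-density mixture.

## Five-class maps, HU assignment, targets

Inside the lungs/air/spine masks the corresponding class membership is
set to 1; elsewhere the mixed-cluster mass is redistributed to fat and
high-density tissue proportionally to their memberships (equal split if
both are zero) — total mass per voxel is conserved. Synthetic CT:
`HU(k) = Σ_j u_jk · HU_j` with the population table air −1000,
lungs −708, fat −89, high-density 39, spine 354; outside the body
−1000 (the surroundings are air). Output values are convex combinations
of the table, hence bounded by [−1000, 354]. A crisp bulk-density
variant maps labels directly through the table. `expand_margin`
performs spacing-aware Euclidean dilation (distance transform ≤ margin)
for CTV→PTV expansion.

## Evaluation

Per class: volumes (voxel count × voxel volume), auto/manual volume
ratio, Dice (defined 1 for two empty masks), and surface-distance
statistics over the pooled symmetric set of nearest
boundary-to-boundary distances (boundary = mask minus its
6-connectivity erosion; distances in mm). Mean and population SD of the
pooled set are reported — the "mean ± SD" convention for boundary
agreement — and the max is the classical symmetric Hausdorff distance.
The summary score is the volume-weighted Dice
`S̄ = Σ_i (V_i/V_T)·S_i` with weights from the *manual* volumes so the
weighting is independent of the algorithm under test; S̄ always lies
between the smallest and largest per-class Dice.

## The digital phantom

The phantom emulates exactly the structure the classifier relies on:
an elliptic-cylinder body (semi-axes 115 × 85 mm) with an 8 mm
subcutaneous fat shell, two lung ellipsoids whose per-slice
cross-sections exceed 3500 voxels near their equators at the reference
1.29 × 1.60 × 4 mm grid, a posterior-central spine (16 mm vertebral
column, spinous-process fin, 5 mm cord cylinder — the cord is labeled
high-density in the truth because the spine class is defined with the
cord removed), and two randomized bowel-gas ellipsoids (10–15 mm)
placed by seeded rejection sampling away from other structures. Channel
intensities are class means (fat-bright adipose, water-bright soft
tissue, near-zero air/lung, balanced marrow) times a smooth
multiplicative bias field (trilinear log-field, max/min ratio 1.3)
plus additive Gaussian noise (SD 15 on a ~400 signal scale). Defaults
are the study conditions; `noise_free()` disables both corruptions.

What the phantom does *not* model: Rician noise statistics, partial
volume at class boundaries, organ shape variability, respiratory
motion, susceptibility/chemical-shift artifacts, and realistic
marrow/cortical-bone substructure (the spine is painted with one
intensity triple). Passing the phantom suite therefore demonstrates
the correctness and internal consistency of the rules and numerics —
not clinical-grade accuracy on patient data, where contrast is weaker
and the published spine Dice (~0.76–0.79) is far below the phantom's.

## Problem sizes and runtimes

The default phantom grid is 192 × 120 × 36 (~0.83 M voxels), chosen as
the package's reference test size; the full pipeline runs in ~10–20 s
on one CPU. Repeated-run property tests (determinism, mask
disjointness across 20 seeds) use a geometrically 0.5-scaled phantom
with the area cutoff scaled by 0.5² and lighter N4/diffusion settings —
the properties checked are scale-free. The acceptance script's
weighted-Dice targets are deterministic computations over five-class
tables and run in milliseconds.

## Known limitations

- Spine growth is 2D per slice; a severely tilted spine would need a
  3D formulation.
- The 3500-voxel filter is resolution-dependent by definition; it is a
  config field and must be rescaled for other in-plane resolutions.
- N4 anatomy leakage (above) slightly perturbs absolute intensities;
  all downstream thresholds are data-derived, which absorbs this.
- Dice of two empty masks is defined as 1; volume ratio against an
  empty manual mask is reported as undefined rather than raising in
  `build_report`.
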