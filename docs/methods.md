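# Methods

## The measurement model

The pipeline reproduces the measurement chain of a light-sheet
(ultramicroscopy) β-amyloid study on cleared APPPS1 mouse brains:

1. **Segmentation.** The intensity volume is binarized at a threshold
   (fixed per volume, or Otsu's inter-class-variance criterion), and
   maximal connected foreground sets become candidate plaques
   (26-connectivity by default, matching the "particle" behavior of 3D
   rendering software; 6 and 18 are available).
2. **Artifact exclusion.** The original workflow excluded blood vessels
   (incomplete perfusion) and fine illumination stripes under manual
   control. Here the exclusion is automated with shape rules: an object is
   flagged *vessel* when its principal-axis elongation exceeds
   `vessel_elongation_max` (default 5) or its longest axis exceeds
   `vessel_length_max_um` (default 100 µm — plaques top out near 70 µm);
   it is flagged *stripe* when its x (illumination-axis) bounding-box
   extent is at least `stripe_anisotropy_min` (default 10) times its
   larger y/z extent. An explicit exclusion mask can be supplied for
   parity with manual workflows.
3. **Counting floor.** Equivalent spherical diameter d = 2·(3V/4π)^⅓ is
   computed from the voxel-count volume V; objects with d < 8 µm are not
   counted (the instrument resolves ~2 µm laterally and ~5 µm axially, and
   resolution degrades toward the field edges, so 8 µm is the safe floor).
   The floor applies to the equivalent diameter, not the bounding box,
   because it is quoted as a diameter. Retained = no artifact flag and
   d ≥ 8 µm; the 8.0 boundary is inclusive.
4. **Stereology.** The cortex volume comes from a mask (or an intensity
   segmentation: Otsu + largest component + closing). Sample cubes are
   fixed to 0.1% of the cortex volume, edge rounded to whole voxels,
   placed seeded-random, non-overlapping, fully inside the mask (the
   original study placed six cubes per animal by hand; no anatomical atlas
   is attempted). A plaque belongs to a cube iff its centroid lies in the
   half-open box [origin, origin+edge) — unbiased for counts and free of
   double-counting; load (volume %) instead uses voxel membership, because
   load is a volume fraction.
5. **Size distributions.** Retained diameters are binned half-open with
   edges 8, 10, 20, 30, 40, 50, ∞ µm: the first bin starts at the counting
   floor so it matches the published 8–10 row; subsequent bins are the
   10 µm size groups. Relative percentages are per animal.
6. **Shrinkage.** BABB clearing shrinks tissue so measured sizes are
   biased ~20% low; interpreting measured = true·(1−s) gives
   corrected = measured/(1−s), s = 0.20 by default. The correction is off
   in pipeline outputs and applied only when flagged, since the published
   distributions are uncorrected.
7. **Statistics.** Between-group comparisons use a two-sided Mann–Whitney
   U (midranks for ties; the null is enumerated exactly over all
   C(n_a+n_b, n_a) labelings when n_a+n_b ≤ 12, otherwise a normal
   approximation with tie and continuity correction). Within-group
   variability uses Kruskal–Wallis with tie correction (χ², k−1 df).
   Asterisks: *** p < 0.001, ** p < 0.01, * p < 0.05, exclusive
   boundaries. Two-sided throughout. The statistical unit between groups
   is the animal (mean over its six cubes), avoiding pseudo-replication;
   per-cube comparisons are also emitted, flagged exploratory. A Welch t
   statistic accompanies the load comparison as supplementary output, so
   both rank-based and t-based readings are inspectable. No
   multiple-testing correction is applied (raw p-values with stars). No
   animal-exclusion rule is implemented; animals with outlying low totals
   are only flagged.

## The synthetic generator

The generator emulates what the microscope sees, not the optics itself
(no ray tracing, refractive-index mismatch, shadowing, or scattering):

- **Plaques** are non-overlapping spheres. True diameters are drawn from a
  `SizeDistributionSpec`: empirical bins (a bin by probability, then
  uniform within the bin) or a truncated lognormal. The built-in adult
  distribution is the published empirical table (8–10: 11.7%, 10–20:
  38.7%, 20–30: 27.7%, 30–40: 21.9%); the young default shifts mass
  toward 20–30 µm (12/40/33/15%), a package choice reproducing the
  qualitative young/adult contrast — no young table is published.
- **Rasterization** defaults to the voxel-centre test (a voxel is plaque
  iff its centre lies inside a sphere), which is exactly testable by
  enumeration. Cohorts rasterize with 2× supersampling: each voxel gets a
  partial-volume intensity background + amplitude·fill, as a CCD pixel
  integrates; thresholding at mid-amplitude then tracks the true surface.
- **Image formation**: constant lateral Gaussian blur (FWHM 2 µm); axial
  blur along z with σ_z(x) = σ_z0·√(1+((x−x₀)/x_R)²), x_R = πw₀²/λ —
  the Gaussian-sheet thickness growth that merges close plaques off-waist;
  optional exponential attenuation e^(−µ·depth) along the depth axis;
  optional Poisson noise plus Gaussian read noise; rounding and clipping
  to the 12-bit camera range (8/16-bit supported). `axial_fwhm_um` (5 µm)
  sets the waist PSF; `sheet_waist_halfwidth_w0_um` (2.5 µm, λ = 0.405 µm
  → x_R ≈ 48 µm) only sets the divergence; they are independent knobs.
- **Artifacts**: vessels are random-walk polylines (3–6 segments) dilated
  to a 3–8 µm radius at plaque intensity; stripes are x-aligned ridges of
  1–2 voxel cross-section at 80% plaque intensity (neither is described
  quantitatively in the literature; these are minimal shapes that trigger
  the exclusion rules). Both are recorded voxel-exactly in the ground
  truth.
- **Cohorts** come in two modes. *Density mode* plants a Poisson number
  of plaques (density × cortex volume) inside an ellipsoidal cortex mask;
  default densities (young 2500/mm³, adult 10000/mm³) are package values
  on the scale implied by the published group totals, not published
  measurements. *Exact-totals mode* plants a requested integer total
  inside pre-declared sample cubes (six per animal, tiled with gaps), so
  the pipeline count is comparable to the planted total with no edge
  ambiguity; cubes are sized so separation-inflated spheres fill 20% of
  the interior, plus a containment margin for the largest sphere.
- **Seeding**: one root seed spawns independent per-group, per-animal,
  placement and imaging streams (`numpy` `SeedSequence`); identical
  config + seed is bit-identical.

Default intensity scale: background 100 counts, plaque amplitude 3000,
Gaussian read noise σ = 20 — high-contrast labeling with ~15% background
noise, the regime in which threshold segmentation is the published method
of choice.

## Validation studies and problem sizes

`amyloidscope.studies` freezes the in-silico experiments used for
validation (run by `tests/test_acceptance.py` and `scripts/acceptance.py`):

- **Diameter sweep**: one sphere per integer diameter 4–60 µm, 2 µm
  voxels, no blur or noise; nothing retained may fall below 8 µm.
- **Planted-total recovery**: exact-totals cohorts planting 4411 (young)
  and 17829 (adult) plaques across 6 cubes × 5 animals, uniform 10–40 µm
  diameters, ≥ 12 µm surface separations, 4 µm voxels, Gaussian noise
  σ = 20 and wide-waist (constant) blur; threshold 1000 counts (far above
  background + noise, far below amplitude, so blur cannot detach small
  plaques). The pipeline count must equal the planted totals exactly.
- **Size-distribution recovery**: 9,999 plaques from the adult empirical
  table over 3 animals × 6 cubes at 2 µm voxels (the narrow 8–10 µm bin
  needs the finer grid), no blur, mid-amplitude threshold; recovered
  8–10 and 10–20 µm bin fractions must sit within 2 percentage points of
  the table. Three animals keep the study inside a desk-scale runtime
  while exceeding the 5,000-plaque floor twofold.
- **Off-waist merging**: pairs of 40 µm spheres 6 µm apart along z,
  imaged at the waist and at 3 x_R off-waist with the default narrow
  waist; the fraction of segmented objects above 50 µm must strictly
  increase off-waist (direction only — the published ~5% figure depends
  on the real plaque field and is not asserted).

## Numerical choices and edge cases

- Threshold ties count as foreground (documented; affects voxel counts at
  the margin). A fixed threshold above the volume's maximum is legal and
  yields an empty segmentation (an animal may genuinely lack plaques).
- Per-object principal axes come from the voxel-coordinate covariance
  regularized by the single-voxel variance (edge²/12 per axis), so a
  one-voxel object has elongation exactly 1 instead of ∞; reported axis
  lengths are 4σ.
- Otsu on a constant image, an empty cortex mask, V ≤ 0, s ≥ 1, empty
  samples in rank tests: all raise typed errors rather than returning
  sentinels. Sphere or cube packing that exhausts its retry budget raises
  a packing error naming the achieved count.
- Empty histograms report zero percentages and set an `empty` flag;
  out-of-range diameters (below the first edge) are excluded from bins.
- Kruskal–Wallis on all-identical data returns H = 0, p = 1 (the tie
  correction would otherwise divide by zero).
- All-NaN-safe: group comparisons with fewer than two animals per group
  report p = NaN with stars "na" instead of failing.

## What passing tests do and do not show

The generator's plaques are ideal spheres with uniform amplitude on a
clean background; real plaques have irregular morphology (three types are
distinguished immunohistochemically), diffuse halos, depth-dependent
signal-to-background decay that defeated fully automatic thresholding in
practice, and anatomy (hippocampus, cerebellum) that this model does not
attempt. Exact planted-truth recovery therefore demonstrates that the
counting chain — rasterization, thresholding, labeling, filtering, cube
stereology — is internally consistent and unbiased under the stated
imaging conditions; it does not certify accuracy on real brains, where
threshold choice and artifact exclusion remain the dominant error
sources. The merging study likewise asserts only the direction of the
Rayleigh-range artifact, not its magnitude.
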