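# Methods

`autorad3d` implements the five-stage processing chain used to turn serial
2D autoradiographs of mouse brains into voxel-wise statistical maps of
cerebral glucose metabolism, together with a synthetic phantom generator
that provides quantitative ground truth for every stage.  This note
records the model assumptions, parameter choices, numerical decisions and
known limitations.

## The processing chain

**1. Cleaning.**  Each digitized 8-bit section is binarized with Otsu's
threshold (exhaustive maximization of the between-class variance over the
256-bin histogram, ties broken toward the lowest threshold for
determinism), opened with a disk structuring element, and reduced to its
largest 8-connected component; everything else (dust speckles,
overlapping stray sections) is set to gray 0 and excluded by the stored
tissue mask.  The opening radius is a physical length (default 50 µm,
i.e. 5 pixels at the 10 µm digitization pitch); it must exceed the dust
speckle radius and stay well below the smallest tissue cross-section.
Polarity (tissue brighter than background) is an explicit parameter
because film positives and negatives both occur in practice.

**2. Calibration.**  The gray→activity (nCi/g) relation is a natural
cubic spline through the co-exposed ¹⁴C standards (≥ 4 points, strictly
monotone in both coordinates; duplicates rejected).  Natural boundary
conditions were chosen because the standards carry no derivative
information at the ends.  On convex standards a natural spline can wiggle
non-monotonically between knots; this is detected on a dense grid and
reported as a warning, never silently.  A linear interpolant is available
as `method="linear"`.  Out-of-range gray levels are clamped to the curve
endpoints by default, mirroring film saturation; a hard-error policy
exists for QC.  One curve per subject film is applied to all of that
subject's sections, since standards and background are shared per film.

**3. Intra-subject reconstruction.**  Sections are stacked along z
(default 20 µm thickness) and realigned sequentially from the centre
outward: the central pair first (the lower central section is the fixed
anchor, so the global pose of a reconstruction is arbitrary), then each
section to its already-aligned inner neighbour, initialized from that
neighbour's final transform to track slowly varying mounting error.  Each
pair is registered with a 3-DOF in-plane rigid transform (tx, ty, θ about
the section centre) maximizing normalized cross-correlation (NCC).  The
metric is evaluated over the whole fixed frame restricted to the in-field
region of the warped section — cleaned sections have background exactly
0, so the tissue outline itself is informative — on mildly Gaussian
pre-smoothed pixels (σ = 2 px), which widens the NCC basin and suppresses
edge-pixelation bias between slightly dissimilar neighbouring sections.
Optimization is two-stage: a deterministic coarse grid search over
translations and angles at 4× downsampling seeds a Nelder-Mead simplex,
followed by simplex refinement at full resolution (cubic interpolation,
spline coefficients prefiltered once).  The returned transform is the
best of {optimum, initialization, identity} under the full-resolution
metric, so alignment can never degrade the starting state and the
reported per-pair NCC never decreases.  Sequential slice-to-slice
alignment cannot observe a smooth global bending of the stack (the
"banana" ambiguity); no 3D reference is used at this stage and the
ambiguity is deliberately left uncorrected.

**4. Inter-subject normalization.**  One reconstructed subject is
designated the template (averaged or unbiased template construction is
out of scope).  The template is smoothed once with a Gaussian of
FWHM = 3 × voxel size per axis (σ = FWHM/2.3548), using mask-aware
normalized convolution so the zero background does not bleed inward.
Each subject is then registered to the smoothed template by a 12-DOF
affine followed by a cubic B-spline free-form deformation, both
maximizing NCC over a 3-level image pyramid (4×, 2×, 1×).

The affine is optimized with L-BFGS-B on an analytic NCC gradient over
the raw matrix entries plus preconditioned translations; it is
initialized by centre-of-mass alignment and restricted to the template
foreground bounding box plus an 8-voxel background margin.  Two numerical
points mattered: (a) no extra pre-smoothing is applied inside the metric —
smoothing both images before resampling measurably biases the optimum
toward contractive maps, because resampling a smoothed image smooths it
again; (b) interpolation is cubic with prefiltered coefficients for the
same reason.  The B-spline displacement is added after the affine
(backward mapping `p → A(p) + D(p)`), optimized with L-BFGS-B on an
analytic gradient obtained by projecting the voxel-wise NCC gradient onto
the separable cubic basis.  The control grid defaults to 1/8 of each axis
extent (never below 2.5 voxels), with one grid-halving refinement
initialized by a separable least-squares fit to the coarse displacement
field.  Grid coarseness is the only regularizer, enforced explicitly by
box-bounding every coefficient at 0.45 × the control spacing (cubic
B-spline fields within that bound cannot fold; without it the
unregularized optimization can grow many-voxel displacements that fold
tissue onto tissue for a marginally higher NCC); no bending-energy term
is used.  Resampling onto the template grid uses linear interpolation for
intensities and majority voting for masks; out-of-field voxels get value
0 and mask 0.

**5. Statistics.**  Normalized volumes are smoothed (FWHM = 3 × voxel
size, mask-aware), then compared voxel-by-voxel with a pooled-variance
two-sample t-test (df = n_A + n_B − 2; Welch available via the library
API), with t > 0 meaning group B > group A.  One-sided p-maps for both
directions are derived from the signed t, so min(p_pos, p_neg) =
p_two_sided/2 exactly.  Voxels with zero pooled variance are excluded and
counted rather than assigned p = 1, so they do not bias the multiple-
testing correction's test count.  FDR control is Benjamini–Hochberg
(step-up over the in-mask p values); FWE control is Bonferroni by
default, with permutation max-T (exhaustive when the number of distinct
relabelings is small, otherwise seeded sampling) as the
dependence-honest alternative.  Significant voxels are grouped into
26-connected clusters, filtered by a user-chosen minimum size, and
tabulated with peak statistic and location.

## The phantom generator

The generator emulates what a real 2DG experiment puts on film, with every random
draw recorded as ground truth:

* **Geometry.**  Each coronal section is one smooth 2D template —
  bilaterally symmetric about the midline like a real coronal section,
  dorsoventrally asymmetric, with a dorsal midline nucleus and a
  bilateral pair of lateral (hippocampus-like) nuclei so in-plane
  rotation is identifiable — concentrically scaled about its own centroid
  by a sinusoidal anteroposterior taper (55–100 % linear size).  Scaling
  about the centroid keeps the change between neighbouring sections a
  pure small zoom, so slice-to-slice rigid alignment has a well-defined
  ground truth.  Structure radii wax and wane by ±20 % along z and uptake
  fades smoothly over the first and last sections, giving the volume real
  anteroposterior features; without them the z-scale of an affine
  registration is nearly unobservable.
* **Rendering.**  All boundaries are analytically soft (logistic profile
  of approximate signed distance, half-width 8 µm, isotropic in physical
  space), emulating film blur and partial-volume averaging.  This matters
  beyond realism: hard stair-cased boundaries leave registration with an
  exploitable pixelation mismatch that biases recovered scales and
  rotations by ~1–2 %.  Consequently the brain rim rolls off toward
  background, so a small band of sub-plateau intensities exists just
  inside the tissue mask.
* **Activities.**  Defaults: tissue 60, dorsal nucleus 110, ventral
  nuclei 140 nCi/g — the range of cortical 2DG uptake — with optional iid
  Gaussian noise (studies default to σ = 3–5 nCi/g).
* **Sectioning.**  Each z-plane is resampled (cubic) under an independent
  in-plane rigid error, tx, ty ~ U(±max_shift), θ ~ U(±max_angle).  The
  defaults for validation studies are ±100 µm and ±5°; no
  quantitative mounting-error magnitudes exist in the literature for this
  preparation, so these are deliberate, configurable choices.
* **Film.**  Activities map to 8-bit gray through the inverse of a
  mildly convex standards curve (activity 0 → film background gray 10),
  quantized round-half-up and clamped at the calibration range (counting
  clamped pixels).  Dust speckles are small bright blobs (gray 150 —
  bright against film background but not so extreme that they form their
  own Otsu class on dim end sections) disjoint from tissue; overlap
  artifacts are shifted copies of a tissue fragment, also disjoint, so
  largest-component selection is the correct remedy.
* **Group studies.**  2 n subjects are drawn with per-subject shape
  jitter (in-plane axes ~ N(1, 1.5 %)) and a smooth multiplicative uptake
  field (sd 3 %, ~10-voxel correlation length) modelling regional
  biological variability.  A global uptake scalar is *not* simulated:
  global film/exposure differences are exactly what the co-exposed
  standards calibration removes, and a shared scalar would make all
  voxel-wise t-statistics of a study perfectly dependent, which no
  voxel-wise method is meant to survive.  Group B is multiplied by
  (1 + effect size) inside the activation region (default: the dorsal
  nucleus); 10–15 % effects mirror the regional increases such studies
  report.

What the phantom does **not** model: exposure-time and film-response
physics, cryostat cutting distortions (tears, folds, compression),
staining variability, and anatomy beyond three nested structures.
Passing tests therefore demonstrate correctness of the algorithms under
idealized image formation, not performance on degraded real film.

## Validation design

* Otsu, BH, the pooled t-test, the natural spline and cluster labelling
  are each checked against independent oracles (exhaustive search, the
  step-up definition and statsmodels, scipy's t-test, a textbook
  tridiagonal solve, brute-force flood fill).
* Reconstruction and normalization are validated by *recovery*: the
  generator records the transforms it applied; registration must invert
  them up to the global anchor pose (reconstruction) or exactly
  (normalization, where the transformed brain is rendered analytically so
  no resampling error enters the ground truth).  Default problem sizes:
  20 phantoms of 64×64×40 voxels for reconstruction, 20 affine draws and
  one B-spline bump at the same size, 8 subjects of 48×48×24 for the
  group-sharpness comparison (judged as NCC of the group-mean warped
  image to the smoothed reference — the actual normalization target —
  with and without the B-spline stage).
* Statistical calibration uses seed-level resampling (20 independent
  studies of 8 vs 8) because smoothing makes voxels within one study
  dependent; the mean suprathreshold fraction is compared to α within
  3 standard errors of the seed-level mean.  For empirical FDR, a
  discovery is counted false when the *true smoothed* effect at that
  voxel is zero — i.e. outside the activation region dilated by the
  smoothing support — because the analysis smooths by design and genuine
  signal extends into that halo; the sensitivity check (Dice of the
  largest surviving cluster) still uses the raw region.
* Determinism is asserted bit-exactly on the full five-step chain run
  twice from one seed.

## Known limitations

* Sequential alignment accumulates a small rotational random walk
  (~0.1°/pair), visible at the outermost sections of long stacks; a
  3D-reference-guided refinement would remove it but is out of scope.
* The anteroposterior (z) scale of the affine is the least constrained
  direction at 20 µm section thickness; recovery to <1 % relies on the
  brain having genuine z-structure, as real brains do.
* The permutation max-T test is uninformative below ~10 distinct
  relabelings (it warns); Bonferroni remains available at any group size.
* NIfTI headers store mm (the format's convention); all internal
  computation is in µm.
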