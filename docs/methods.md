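# Methods

This note documents the models and procedures mrikit implements, the
defaults and why, what the synthetic phantoms do and do not emulate, and
the design choices made where the design was genuinely open.

## Data model and units

An `ImageVolume` is a 2–5 dimensional float64 array ordered
(x, y, slice, echo/time, repetition) plus acquisition geometry: in-plane
voxel sizes `voxel_x`, `voxel_y` (mm), `slice_thickness` (mm) and
`slice_gap` (mm, the inter-slice distance covered by neither slice).
Echo/repetition time lists are in ms. Voxel indices are 0-based, the
slice axis is always the 3rd array dimension, and areas/volumes are
reported in mm²/mm³. NIfTI-1 headers carry the voxel sizes; the slice gap
and TE/TR lists travel in a JSON sidecar because the NIfTI header has no
reliable slot for them. Precedence is deterministic: header pixdim wins
for voxel sizes unless a sidecar key explicitly overrides it; the sidecar
is the only source for slice gap and timing lists. Sessions persist as a
directory of NIfTI files plus a JSON manifest — inspectable from any
language, with bit-exact array round-trips.

## Brain extraction

Intensity-only K-means with k = 2 separates bright brain tissue from dark
background in T2-weighted rodent images after a rough initialization of
the brain area (a user-drawn or programmatically produced outline).
Choices:

- **Feature = raw voxel intensity.** No texture or spatial features; the
  intensity contrast does the work and keeps the method transparent.
- **Clustering restricted to the outline's bounding box dilated by 20%**
  per axis. Background far from the head would otherwise dominate the
  clusters and slow convergence.
- **k-means++ initialization, caller-supplied seed, ≤ 100 iterations,
  relative centroid tolerance 1e-4** (`n_init = 10`). Results are
  deterministic for a fixed seed.
- **Cluster selection by Dice against the outline.** The winning cluster
  is the one maximizing SDSC = 2|M_cl ∩ M_ba| / (|M_cl| + |M_ba|). An
  exact tie is broken toward the higher mean intensity, since brain is
  bright on T2.
- **Per-slice mode** reruns K-means per slice; cluster labels are
  renumbered by ascending centroid intensity so label semantics are
  consistent across independent slice runs.
- **Both-empty Dice is defined as 1** (complete similarity of empty sets)
  and flagged as degenerate; the 0/0 case cannot otherwise be ordered.

Refinement is binary opening and/or closing with a flat disk (integer
radius ≥ 1), applied slice-wise even to 3D masks — slice-based
acquisitions are anisotropic (0.1 mm in-plane vs 0.5+ mm through-plane),
so a 2D disk is the geometrically meaningful element. Opening never adds
voxels and closing never removes them; both are idempotent. Default
pipeline order is opening then closing; both steps are optional.

Manual corrections are polygons (a freehand stroke is just a many-vertex
polygon). A voxel belongs to a polygon when its center lies inside by the
even-odd rule; vertices are continuous (x, y) voxel coordinates, so a
square from (1.5, 1.5) to (5.5, 5.5) captures exactly the 16 voxel
centers (2..5, 2..5).

## Hemispheres and ROIs

Hemisphere masks are polygon rasterizations intersected with the brain
mask — every hemisphere voxel must be a brain voxel. Auto-completion
defines the contralateral mask as brain \ ipsi, which guarantees the two
set identities ipsi ∪ contra = brain and ipsi ∩ contra = ∅ exactly.

ROI region growth uses the morphological Chan–Vese active contour
(region-based energy, smoothing 1) evolved from a seed mask for a fixed
iteration count; it is deterministic. On a contrast-free (constant) image
there is no energy gradient and the seed is returned unchanged — this
degenerate behavior is defined rather than left to the optimizer.
Supervoxel partitioning is a thin contract over SLIC with
`compactness = 0.05` by default: low compactness weights intensity over
spatial regularity, which is what makes supervoxels track anatomical
boundaries; the label count is guaranteed within a factor of two of the
request and labels are spatially connected.

## Volumetry

Total mask volume is `N·V_vox + CV_gap` with
`V_vox = X_vox·Y_vox·thickness`. `CV_gap` sums `A_gap·slice_gap` over the
gaps whose two adjacent slices are both non-empty, with
`A_gap = (N_back + N_front)/2 · X_vox·Y_vox` — the gap's cross-section is
estimated as the mean of the flanking slice areas. Gaps next to an empty
slice contribute nothing (the mask evidently ends there).

Summary statistics (mean, SD, median, IQR, min/max) are computed over the
masked voxels; IQR is Q3 − Q1 with linear-interpolation quantiles
(quantile conventions differ across ecosystems, so this is pinned). An
empty mask yields NaN statistics with `n_voxels = 0`, not an exception.

Edema correction operates per slice on areas, given ipsi- and
contralateral hemisphere masks:

- Reglodi: `A_corr = A_orig · A_contra / A_ipsi`
- Belayev: `A_corr = A_orig · (1 − (A_ipsi − A_contra)/A_contra)`
- Gerriets (area-modified):
  `A_corr = (A_c + A_i) − (A_c + A_i − A_orig) · (A_c + A_i) / (2 A_c)`

All three are the identity for symmetric hemispheres — the algebraic
check used throughout the tests. The Gerriets expression is
parenthesized so that this identity holds; with grouping ambiguity in
typeset sources, the symmetric-hemisphere identity is the discriminating
property. Negative corrected areas (possible for Belayev when
A_ipsi > 2·A_contra and for Gerriets under large asymmetry) are *not*
clamped: they propagate with a warning, because clamping would silently
change the published formulas, and the caller may legitimately want the
raw value. For the same reason Belayev's monotonicity in A_orig only
holds while A_ipsi < 2·A_contra, and the property test is restricted to
that regime. Slices with an empty ROI contribute a corrected area of 0
and skip the hemisphere ratio entirely, so they can never raise a
division error. The corrected volume is Σ A_corr·thickness plus the gap
rule applied to the corrected areas (gaps flanked by nonzero corrected
areas on both sides).

## Relaxometry and pASL

Signal models: `S0·exp(−TE/T2)` (multi-echo), `S0·(1 − exp(−TR/T1))`
(saturation recovery) and `|S0·(1 − 2exp(−TI/T1))|` (inversion recovery
on magnitude data). Each masked voxel is fitted independently with
Levenberg–Marquardt (scipy `least_squares`, `method="lm"`) using analytic
Jacobians; the magnitude model's Jacobian carries the sign of the inner
expression, which is exact except on the measure-zero null crossing.

Numerical choices:

- **Normalization**: each voxel's series is divided by its maximum before
  fitting and S0 rescaled afterwards. This conditions the optimizer
  uniformly across voxels and makes fitted T1/T2 invariant to uniform
  signal rescaling (verified by test).
- **Initialization**: T2 from a two-point log-linear estimate on the
  first/last echoes; T1 from the timing point nearest half recovery
  (saturation) or nearest the magnitude null (inversion), divided by
  ln 2. Degenerate estimates fall back to the mid-timing value.
- **Bounds** T ∈ [1, 10000] ms, S0 ≥ 0, enforced by projecting the LM
  solution; a projected voxel is flagged non-converged (LM itself is
  unbounded, and a solution at the wall means the model did not explain
  the data — e.g. a constant series drives T2 to the upper bound).
- **Tolerances** xtol = ftol = gtol = 1e-8, ≤ 200 iterations. Noiseless
  synthetic series are recovered to ≲1e-15 relative, far inside the 1e-6
  documentation tolerance.

pASL: the acquisition gives inversion-recovery series under
slice-selective (labeled) and global (control) inversion. Perfusing blood
shortens the selective apparent T1, so after fitting T1_sel and T1_glob
voxelwise the map is the FAIR rate difference scaled by blood T1:

    f_rel = (λ/α) · T1_blood · (1/T1_sel − 1/T1_glob)

This specific two-parameter-fit-then-rate-difference form is a modeling
choice of this package; the partition coefficient λ and inversion
efficiency α default to 1, giving *relative* perfusion maps. Absolute CBF
calibration (units mL/100 g/min) is the caller's responsibility via those
constants. Identical labeled and control series give exactly zero
everywhere.

## Registration

Engines are pluggable through a two-method contract (`register`,
`apply`); a transform is a JSON-serializable dict, and re-applying it to
the original moving image reproduces the warped output bit-for-bit
(register internally produces its output through `apply`, making the
invariant structural). The built-in engine recovers in-plane rigid
motion: phase cross-correlation (upsampling factor 20, ~0.05 voxel
resolution) for translation, plus a coarse (1°) then fine (0.1°) grid
search over rotation within ±15°, scored by normalized cross-correlation.
This covers motion correction of slice-based time series, where movement
is small and in-plane by assumption; affine and B-spline non-rigid models
are deliberately *not* implemented by the built-in engine (requesting
them raises a capability error) — an external engine can provide them
through the same contract.

The two-step "parameter image" workflow registers a raw acquisition
(reliable contrast) to the fixed image and re-applies — never
re-estimates — that transform to the derived, low-contrast parameter map
sharing the raw data's grid. Time-series alignment registers each frame
independently to the chosen reference frame (returned unchanged), so the
result is order-independent and trivially parallelizable. Resampling is
linear for images and nearest-neighbor for masks and label maps.

## Synthetic phantoms

The generator produces every input the pipelines need, with exact ground
truth:

- **Structural**: an axis-aligned ellipsoidal "brain" (default semi-axes
  35% of each dimension, intensity 1000) on background 50 — a contrast of
  950, similar in spirit to T2-weighted rodent brain/background contrast
  — with hemispheres split at the mid-sagittal plane, an optional lesion
  ellipsoid in the ipsilateral hemisphere (intensity 1400), and an
  `edema_scale` that inflates the ipsilateral half's in-plane extent to
  emulate swelling. Default grid 64×64×10 at 0.1×0.1×0.5 mm. Masks are
  the exact voxel-center-inside-ellipsoid rasterizations.
- **Relaxation series**: the exact forward model evaluated on truth maps
  at the given TE/TR/TI list (defaults used in tests: T2 = 50 ms over
  TE = 10..80 ms; T1 = 1500 ms over TR = 300..6000 ms or 8 TIs spanning
  100..4000 ms; S0 = 1000).
- **Motion series**: a base frame rigidly moved per frame by known
  (dx, dy, θ), θ limited to ±30°.

Noise is additive Gaussian from `numpy.random.default_rng(seed)`, drawn
in a single call over the full array — identical seeds give identical
data on any platform. Magnitude-MRI noise is properly Rician; at the
SNRs used (σ up to 10% of contrast) the Gaussian approximation is
standard, and it keeps ground truth exactly known. The phantoms do *not*
emulate anatomy, partial-volume edges, intensity inhomogeneity (B1/B0),
EPI distortion or through-plane motion, so passing tests demonstrate the
correctness of the algorithms and formulas, not expected accuracy on real
animals — segmentation quality on real data depends on contrast and
operator outlines in ways a two-intensity phantom cannot probe.

## Problem sizes

Tests and the acceptance script run at desk scale: 64×64×10 phantoms for
segmentation, ~500 voxels for noisy fit-recovery statistics, 64×64 frames
for registration. These sizes are far past the point where the measured
quantities stabilize (the Dice and recovery medians change in the fourth
decimal between seeds) while keeping the whole suite at a few seconds.

## Known limitations

- Bruker ParaVision/DICOM import is out of scope; any loader returning an
  `ImageVolume` slots in ahead of the pipelines.
- The built-in registration engine is rigid and in-plane; 3D rotation and
  non-rigid models need an external engine.
- No DSC (CBF/CBV/MTT deconvolution), multi-compartment relaxometry, or
  B1/B0 correction.
- Edema correction assumes the ROI lies inside the ipsilateral
  hemisphere; it refuses (with the offending slices listed) otherwise.
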