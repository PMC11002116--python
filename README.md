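# mrikit

Scriptable analysis of preclinical (rodent) brain MRI: brain, hemisphere
and ROI segmentation, slice-gap-aware volumetry with edema correction,
voxelwise T1/T2 relaxometry, pulsed-ASL relative perfusion mapping, and
rigid image registration — as a Python library plus a `mrikit` command-line
tool. It is aimed at experimental neuroimaging groups who work with
multislice 2D acquisitions (stroke and TBI models, relaxometry series,
ASL perfusion) and want a reproducible, GUI-free pipeline.

## What it computes

**Brain extraction.** Voxel intensities inside (a dilated bounding box of)
a rough user-supplied brain outline are clustered with K-means (k = 2 by
default, per slice or volumetric). The brain cluster is selected by the
Sørensen–Dice similarity coefficient against the outline,

SDSC = 2 |M_cl ∩ M_ba| / (|M_cl| + |M_ba|),

and refined by morphological opening/closing with a flat disk. Polygon
(or dense-polygon "freehand") corrections, hemisphere intersection with
auto-completion of the contralateral side, Chan–Vese active-contour region
growth and SLIC supervoxels cover the rest of the masking workflow.

**Volumetry.** A mask's volume is `N·V_vox + CV_gap` with
`V_vox = X_vox·Y_vox·thickness`; the slice-gap correction adds, for every
gap flanked by non-empty mask slices on both sides, the gap width times
the mean of the two adjacent slice areas. Lesion areas can be corrected
per slice for hemispheric edema by three published methods (Reglodi,
Belayev, area-modified Gerriets), all of which reduce to the identity for
symmetric hemispheres.

**Parameter maps.** Voxelwise Levenberg–Marquardt fits with analytic
Jacobians of `S0·exp(−TE/T2)`, `S0·(1 − exp(−TR/T1))` or magnitude
inversion recovery `|S0·(1 − 2exp(−TI/T1))|`; pASL relative perfusion is
the FAIR-type rate difference `T1_blood·(1/T1_sel − 1/T1_glob)` from two
apparent-T1 fits.

**Registration.** A pluggable-engine design with a built-in in-plane rigid
engine (phase-correlation translation plus a coarse-to-fine rotation
search), a two-step "parameter image" workflow for low-contrast derived
maps, and rigid time-series motion correction.

Everything is testable against a built-in deterministic phantom generator
with exactly known ground truth.

## Worked example

```python
import numpy as np
from scipy import ndimage
from mrikit import (PhantomSpec, make_structural_phantom, BinaryMask,
                    kmeans_segment, morph_open, morph_close,
                    StructuringElement, dice, mask_volume)

spec = PhantomSpec(shape=(64, 64, 10), noise_sigma=95.0, seed=7)  # 10% noise
vol, truth = make_structural_phantom(spec)

outline = BinaryMask(ndimage.binary_dilation(truth["brain"].data, iterations=3))
mask = kmeans_segment(vol, outline, k=2, seed=0)
mask = morph_close(morph_open(mask, StructuringElement(2)), StructuringElement(2))

print(f"Dice vs ground truth: {dice(mask, truth['brain']).value:.4f}")
print(f"brain volume: {mask_volume(mask, vol.geometry):.3f} mm^3")
```

prints

```
Dice vs ground truth: 0.9989
brain volume: 35.880 mm^3
```

i.e. the extracted brain overlaps the ground-truth ellipsoid almost
perfectly (Dice 0.999), and its volume — voxel count times the 0.1 × 0.1
× 0.5 mm voxel volume, no slice gap here — is 35.88 mm³ against a
ground-truth volume of 35.96 mm³.

The same pipeline from the shell:

```sh
mrikit phantom --out ph --shape 64 64 10 --noise-sigma 95 --seed 7
mrikit segment --image ph/image.nii.gz --outline ph/outline.nii.gz \
               --out brain.nii.gz --open-radius 2 --close-radius 2
mrikit volume --image ph/image.nii.gz --mask brain.nii.gz --out stats.csv
```

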