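# coroseg

Automatic segmentation of coronary arteries from contrast-enhanced CT
angiography (CTA) volumes, with a complete synthetic-phantom test bed and an
evaluation suite.

In CTA the contrast-filled coronary lumen is bright (≈300–400 HU) against
myocardium and fat, but the arteries are thin (1–3 mm), branch repeatedly,
and connect to the far larger aorta, so naive thresholding or unconstrained
region growing either fragments the tree or floods the blood pool.
`coroseg` implements a multi-stage pipeline for this problem:

1. **Seed detection.** The aorta changes little between adjacent axial
   slices; a connected component that newly appears next to it in a slice
   marks a coronary ostium. Seeds are found from per-slice set differences
   of the bright-structure masks.
2. **Capped 3D region growing.** 26-connected growth from the seeds merges
   a voxel `v` when `|I(v) − mean(region)| ≤ τ`, with the region mean
   updated incrementally. To control leakage, a pass is capped at 12 000
   voxels; hitting the cap tightens τ and restarts. The known aorta is
   excluded so growth follows the coronary tree. The result is dilated by
   3 voxels into a region of interest (ROI).
3. **3D Haar DWT + neutrosophic transform.** A one-level separable Haar
   DWT splits the volume into eight subbands `LLL…HHH`. Each HHH
   coefficient is mapped to a neutrosophic triple — truth
   `T = (H̄ − H̄_min)/(H̄_max − H̄_min)` from the local window mean `H̄` of
   `|HHH|`, falsity `F = 1 − T`, and indeterminacy `U` from the normalized
   deviation `|HHH − H̄|`. The α-means operation replaces `T`, `F` by their
   `w³` local means wherever `U ≥ α` (defaults: `w = 3`, `α = 0.2`), and
   the inverse DWT of the `T`-weighted subbands yields a "true" volume in
   which boundary texture is kept and incoherent noise suppressed.
4. **K-means classification.** ROI voxels of the true volume are clustered
   by intensity into K = 3 classes (background / vessel boundary / vessel
   lumen, ordered by cluster center); the vessel classes, restricted to the
   ROI and minus the aorta, form the final mask.

Scoring uses the overlap metric `OM = 2|N_T ∩ N_R| / (|N_T| + |N_R|)`
(Dice), the boundary Hausdorff distance
`d_H(X,Y) = max{sup_x inf_y d(x,y), sup_y inf_x d(x,y)}` in mm, and
centerline-based calibre estimation: after medial-axis thinning, the
cross-section area `A` orthogonal to the local tangent gives the
equivalent-circle radius `√(A/π)`.

Because no public CTA dataset accompanies the method, the package ships a
phantom generator (`coroseg.phantom`) producing CTA-like volumes — a 12 mm
aorta cylinder, four tapering coronary branches (start radii 2–3 mm at
0.625 mm isotropic voxels), 50/350 HU contrast, Gaussian noise — with exact
ground-truth masks, centerlines and radii.

## Worked example

```python
from coroseg import (PhantomConfig, PipelineConfig, hausdorff, make_phantom,
                     overlap_metric, overlap_metric_2d, run_pipeline)

truth = make_phantom(PhantomConfig(rng_seed=1))
result = run_pipeline(truth.volume, truth.aorta_mask, PipelineConfig(rng_seed=0))
print(overlap_metric(result.vessel_mask, truth.vessel_mask))      # 3D Dice
print(overlap_metric_2d(result.vessel_mask, truth.vessel_mask))   # mean per-slice
print(hausdorff(result.vessel_mask, truth.vessel_mask))           # mm
```

Running `python examples/02_segment_phantom.py` (the same computation with
stage logging) prints:

```
{'stage': 'detect_seeds', 'provided': False, 'n_seeds': 605, 'slice_index': 15}
{'stage': 'grow', 'n_voxels': 6768, 'tau_used': 83.32, 'restarts': 0, 'capped': False}
{'stage': 'dilate', 'radius': 3, 'n_voxels': 42492}
{'stage': 'classify', 'k': 3, 'centers': [42.5, 59.5, 348.6], ...}
3D overlap metric : 1.0000   (1.0 = perfect volumetric match)
mean 2D overlap   : 1.0000   (per-slice Dice, vessel slices only)
Hausdorff distance: 0.000 mm (largest boundary disagreement)
```

The detected ostia seed 6 768 voxels of growth (well under the 12 000-voxel
leakage cap), and with the phantom's 300 HU vessel/background contrast
against σ = 10 noise the classifier recovers the tree exactly. The other
scripts in `examples/` demonstrate phantom generation, wavelet texture
probing, and centerline/diameter measurement.

A thin CLI wraps the same API:

```
coroseg phantom --seed 1 --out ph/
coroseg segment --in ph/volume.nii.gz --aorta ph/aorta_mask.nii.gz --out seg.nii.gz
coroseg eval --pred seg.nii.gz --truth ph/vessel_mask.nii.gz --report report.json
```

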