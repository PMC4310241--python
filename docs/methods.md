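# Methods

This note records the model implemented by `coroseg`, the parameter
defaults and why they were chosen, the numerical conventions that matter
for reproducibility, and what the synthetic phantom does and does not test.

## Pipeline model and assumptions

The method assumes a contrast-enhanced CTA volume in which the aortic and
coronary lumens are bright and roughly homogeneous, the coronary tree is
connected to the aorta at its ostia, and vessel boundaries are the dominant
fine-scale structure in their neighbourhood. It further assumes an aorta
mask is available (from upstream preprocessing or, for phantoms, from the
generator); `coroseg.region_growing.bright_structure_mask` provides a
simple Otsu-threshold fallback for building per-slice bright masks, but it
is a pragmatic utility, not a validated aorta detector.

**Seed detection.** Per-slice bright masks are differenced between
adjacent slices `(k, k+1)`; an 8-connected component of the difference with
area ≥ `min_new_area` (default 5 px) touching the persisting structure is
an ostium candidate. `detect_seeds` returns the first qualifying pair;
`detect_seeds_all` (used by the pipeline) scans all pairs, because branches
arise at different heights and each ostium must seed growth. Branches
oriented *against* the scan direction would present their distal tip, not
an ostium, and be missed — the pipeline scans ascending z and assumes
ostium-first geometry, which holds for coronaries in standard axial
ordering.

**Region growing.** FIFO queue, 26-connectivity, candidates enqueued in a
fixed lexicographic neighbour order; a voxel is accepted when its intensity
is within τ of the running region mean, which is updated after every
acceptance; a voxel rejected once is never reconsidered. These choices make
the result bit-for-bit reproducible. τ defaults to 0.25× the robust
(1st–99th percentile) intensity range of the seed slice, so it scales with
acquisition contrast. A pass is capped at 12 000 voxels; on a cap the
criterion is "improved" by tightening τ ← 0.7·τ and restarting, up to 5
times, after which the capped result is returned with a `RuntimeWarning`.
The aorta mask is passed as a forbidden region: the aorta is as bright as,
and connected to, the coronary tree, so unconstrained growth would spend
the entire cap flooding it. For the same reason the final mask excludes
the aorta.

**Wavelet stage.** One-level separable Haar DWT (filters
`h = (1/√2, 1/√2)`, `g` by the quadrature-mirror relation), downsampling by
two per axis, eight subbands `LLL…HHH` with the first label letter
attached to the x axis (array axis 0). Odd-length axes are zero-padded by
one sample and the original shape recorded so the inverse crops exactly.
Zero padding was chosen over symmetric extension deliberately: with the
orthonormal Haar pair it keeps *both* perfect reconstruction and exact
energy conservation (Parseval) on every shape, whereas symmetric extension
duplicates the edge sample and inflates the subband energy of odd axes by
several percent. Generic orthonormal filter pairs are accepted through
`WaveletSpec`, but only Haar is exercised by the tests.

**Texture search.** The per-channel statistic is the size-normalized
l2-norm `‖C‖₂/|C|` of each of the seven detail channels; the search stops
at the first level where the largest statistic is ≥ 1.5× the second
largest ("significantly greater" needs a concrete, testable rule; 1.5 on
averaged channel norms is that rule, and `LLL` is excluded since the
approximation band trivially dominates). If no level up to `max_levels`
produces dominance, the argmax at the last level is returned flagged
non-dominant. On volumes whose texture alternates at the voxel scale in
all three axes (checkerboard-like) the search returns HHH at level 1; on
smooth digitized tubes the surface energy concentrates in the single-axis
high-pass channels of the local normal instead, and no channel dominates —
see "Limitations" below. The pipeline therefore treats the search as an
optional diagnostic (`texture_check`) and always processes HHH, the
channel that carries voxel-scale boundary texture by construction.

**Neutrosophic stage.** With `H̄` the `w³` local mean of `|HHH|`
(`w = 3`): `T = (H̄ − H̄_min)/(H̄_max − H̄_min)`, `F = 1 − T`,
`U = (δ − δ_min)/(δ_max − δ_min)` with `δ = |HHH − H̄|`. Averaging the
*magnitude* is the default because signed Haar detail coefficients average
to ≈0 in any textured region, which would make `T` noise rather than a
texture-strength measure; the literal signed average is available as
`magnitude_mode="raw"`. Two window conventions are provided: `centered`
(default; the standard local mean, borders replicated) and `literal` (the
forward-shifted bounds `l ∈ [i, round(i+w/2)]`, which for `w = 3` cover
exactly `w` samples per axis). α-means is applied exactly once — there is
no convergence criterion to iterate on — replacing `T`, `F` by their local
means where `U ≥ α` (default `α = 0.2`), after which `U` is recomputed as
the normalized deviation of the smoothed truth field and `F = 1 − T` is
re-enforced. Degenerate normalizations (max = min) yield the zero grid.
Note the recomputed `U` lives on its own min–max scale: the *mean*
indeterminacy never increases, but the count of voxels above a fixed α
may, since the normalization denominator shrinks along with the
deviations. Mapping the final `T` back onto coefficients before the
inverse DWT is underdetermined; the default multiplies HHH by `T`
(`mode="weight"`, an attenuation that is the identity at `T = 1`), and
`mode="rescale"` (map `T` back through the stored local-mean range,
keeping signs) is provided as the alternative interpretation.

**Classification.** ROI voxels of the reconstructed volume are clustered
on their 1-D intensity by K-means (K = 3): Lloyd iterations from
k-means++ seeds, 10 restarts with sub-seeds spawned deterministically from
one integer, empty clusters repaired by reseeding to the farthest point.
Clusters are ordered by center: lowest = background, middle = boundary,
highest = lumen; `classify_roi` reports `vessel = lumen ∪ boundary`.
Whether the middle cluster really is vessel depends on the data: when the
image contains a genuine partial-volume boundary class its center sits in
the upper half of the background–lumen interval, but on strictly two-valued
data (such as the no-anti-aliasing phantom) K = 3 must split one of the
two modes, and it splits whichever has the larger population × variance —
in a dilated ROI that is the background shell, whose upper noise tail then
masquerades as "boundary". The pipeline's `boundary_rule="auto"` resolves
this adaptively: the middle cluster counts as vessel iff its center lies at
or above the midpoint of the background and lumen centers. This reduces to
the union rule exactly when the middle cluster is genuinely bright, and to
lumen-only when it is a background artifact. `"union"` and `"lumen"` are
available to force either behaviour.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| τ (grow) | 0.25 × robust range of seed slice | scales with contrast; ≈75 HU on a 300 HU phantom |
| cap | 12 000 voxels | leakage bound on one growing pass |
| tighten factor | 0.7 | multiplicative τ tightening on restart |
| max restarts | 5 | after which the capped mask is returned with a warning |
| dilation radius | 3 voxels | ROI margin around the initial segmentation |
| w | 3 | local window of all neutrosophic means |
| α | 0.2 | indeterminacy threshold of α-means |
| K | 3 | background / boundary / lumen |
| dominance ratio | 1.5 | texture-search stop rule |
| `min_new_area` | 5 px | smallest ostium cross-section accepted as a seed |

## The phantom

Defaults: 128³ voxels at 0.625 mm isotropic; a 12 mm-radius aorta cylinder
through the volume center; four branches leaving the aortic wall at
distinct heights and azimuths, piecewise-linear with a predominant +z
(descending) direction, 35 mm long, start radii 3.0/2.65/2.35/2.0 mm
tapering linearly to half; background 50 HU, vessels 350 HU, additive
Gaussian noise σ = 10. The branch lengths and radii give a tree of ≈6–7 k
voxels — the anatomically plausible proximal-segment scale, and inside the
12 000-voxel cap, matching the regime where growing completes without
leakage restarts. Everything is deterministic given `rng_seed`.

Ground truth: a voxel is vessel iff its center lies within the analytic
tube radius of the nearest centerline sample and outside the aorta
cylinder (the coronary begins at the ostium). Stored centerlines are
trimmed to a radial distance of aorta radius + local tube radius so every
stored point, and every voxel within `r − 1` voxel of it, is guaranteed
inside the vessel mask. The full untrimmed analytic paths are kept
alongside (`paths_mm`) for volume oracles.

What passing on phantoms shows — and does not. The phantom exercises the
geometry and logic of every stage: ostium detection, leakage-capped
growth, subband bookkeeping, membership formulas, cluster ordering, and
the metrics. It does **not** emulate partial-volume edges, reconstruction-
kernel noise correlation, heart chambers and veins adjacent to the
coronaries, motion or beam-hardening artifacts, or calcified plaque.
Scores on phantoms are therefore upper bounds: with 30σ contrast and
binary edges the pipeline recovers the tree essentially exactly, which
validates correctness of the machinery, not clinical accuracy.

## Numerical choices and degenerate inputs

- Volumes are float64 throughout; masks are boolean grids with spacing.
- Index convention `(i, j, k) = (x, y, z)`; a "slice" is a fixed-k plane.
- One global pipeline seed fans out via `SeedSequence([seed, stage])`.
- Growing: ties never arise (FIFO + fixed neighbour order); seeds are
  accepted unconditionally; all-seed-forbidden input is an error.
- K-means on fewer distinct values than K is flagged `degenerate`;
  repaired clusters that remain empty keep their center.
- `overlap_metric` of two empty masks is defined as 1; `hausdorff` of an
  empty mask is an error. Hausdorff uses boundary voxels (≥1 background
  6-neighbour; the volume border counts as background) scaled by spacing —
  boundary-voxel centers, not a triangulated mesh, which avoids a meshing
  dependency and is deterministic.
- The 2D overlap is the mean of per-slice Dice over slices where the
  *reference* is non-empty; the 3D overlap is the single volumetric Dice.
- Centerlines: medial-axis thinning (topology-preserving), polylines split
  at voxels with ≥3 skeleton neighbours. Thinning erodes up to about one
  tube radius from an open tube end, so measured skeleton lengths
  undershoot the analytic axis length by up to `2r`.
- Diameters: the cross-section is sampled at 0.2 mm pitch on the
  orthogonal plane, restricted to the in-plane connected component
  containing the centerline point (so a plane clipping a neighbouring
  branch does not inflate the area). The reported value is the
  equivalent-circle radius `√(A/π)`; the conventional diameter `2√(A/π)`
  is available via `circle_equivalent_diameter=True`. The report always
  states units.

## Acceptance computation

`scripts/acceptance.py` generates ten phantoms (default configuration,
per-phantom seeds derived from `--seed`), runs the full pipeline with the
default configuration, pools per-slice Dice over all vessel-containing
slices (~1 000 slice evaluations), and writes the mean. The 128³ problem
size keeps the whole computation around a minute on one CPU while
preserving the full multi-branch geometry.

## Known limitations

- The HHH-dominance claim for vessel texture is not reproducible on
  geometric tube phantoms: smooth digitized surfaces put their energy into
  the single-axis high-pass channels of the local normal, and white noise
  is flat across channels, so `texture_search` on phantom vessel ROIs
  returns an HLL-family channel without dominance. Reproducing the claim
  would require the voxel-scale texture statistics of real CTA.
- The aorta must be supplied; automatic aorta detection is out of scope.
- No DICOM series assembly (convert to NIfTI/MetaImage first), no mesh
  surface distances, no stenosis quantification.
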