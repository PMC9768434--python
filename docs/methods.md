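# Methods

This note records the model as implemented, the parameters that matter, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and known limitations.

## The threshold-surface model

ILEE treats segmentation as harmonic interpolation constrained at filament
edges. With `S` the 0/1 diagonal selection of edge pixels (Scharr gradient
magnitude strictly above `g_thres`) and `L` the weighted graph Laplacian of
the pixel lattice, the threshold surface solves

    (S + K L) x = S I_pre .

This form has the properties the method relies on: a constant image is an
exact fixed point for every `K` and selection; as `K → 0⁺` the surface pins
the anchors to their preprocessed intensities; as `K → ∞` it flattens toward
the anchor mean (the span `max x − min x` is monotone non-increasing in `K`).
The transposed form `(L + K S) x = S I_pre` satisfies none of these and
classifies essentially the whole image as signal; it is retained behind
`solve_threshold_surface(..., system="LKS")` only for forensic comparison.

Laplacian weights: 2D default is 8-connectivity (orthogonal −1, diagonal
−√2/2, interior centre 4 + 2√2; a 4-connectivity variant is available), 3D is
6-connectivity. Border rows always sum to zero (the diagonal is the sum of
the neighbours actually present).

If no pixel exceeds `g_thres` the lattice has no anchor; the surface is set
to +∞ and the image is classified entirely as background. This is the only
meaningful output for a structure-free input (see Limitations).

### Solver

The system is symmetric positive definite whenever at least one pixel is
selected. 2D lattices up to ~400k pixels are factorised directly (SuperLU).
Larger problems use conjugate gradients at relative tolerance 1e-8 (iteration
cap 50 000; non-convergence raises with the residual). Because the anchors
cluster on filament edges, plain Jacobi-preconditioned CG is dominated by the
long-range harmonic fill of anchor-free regions (~400+ iterations on a
64×256×256 stack); CG is therefore preconditioned with a Galerkin multigrid
V-cycle (piecewise-constant prolongation, damped-Jacobi smoothing, direct
coarsest solve), which reaches the same tolerance in ~20 iterations. This is
purely an implementation choice: the system and tolerance are unchanged.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k1` | 2.5 | smoothing weight of the thin/faint-filament pass; the finest resolvable filament is ~1 px, so this is fixed |
| `k2` | estimated | smoothing weight of the thick-bundle pass; `log10 K2` is affine in the batch-mean top-5% distance-transform statistic of a Niblack binarisation (window `2·int(l/25)+1`, `k = −0.36`); floored at `k1` |
| `sdf_sigma_mult` | 2 (2D), 5 (3D) | outlier-replacement threshold of the significant-difference filter, in surround SDs |
| `gaussian_sigma` | 0.5 | 3×3(×3) smoothing kernel; 3D kernel re-weighted by `O_scalar` (outer z-slices ×f, global 3/(1+2f)) and renormalised |
| `min_element_size` | 3 | positive difference components smaller than this are reset to the mean negative difference |
| `oversample_factor` | 3 | cubic-spline upsampling of the difference image before the zero threshold |
| `connectivity_2d` | 8 | Laplacian neighbourhood |
| anisotropy probe radius | 20 native px | ball radius for the local alignment tensor; probe centres on a regular grid of the same spacing |
| chord length | 5 px | straight-segment decomposition of skeleton branches for the tensor |

All lengths are micrometres; the voxel geometry (`u_xy`, `u_z`) comes from
TIFF metadata or an explicit override, and `f = u_xy/u_z`.

## Background models and their calibration

NNES counts *non-connected negative elements*: maximal sub-threshold runs
along image rows. For iid noise the run density is `p(1−p)` at sub-threshold
probability `p`, so the count peaks exactly at the noise median/mode — the
property that makes `x_peak` a robust background feature. (Lattice
component labeling would peak at the `p ≈ 0.27` quantile instead and shift
every downstream regression.) The scan uses integer grayscale steps; when
the full range would exceed 512 steps, a 128-point coarse pass brackets the
peak and its 80% band, which is then re-scanned at unit step.

The Scharr magnitude is the Euclidean norm of the per-axis responses divided
by a fixed constant: 32/√2 in 2D, 30× that in 3D. The 2D constant is the one
(among the plausible readings of the printed normalisation) under which iid
normal noise reproduces the calibrated coefficients `mean|G| = 0.8542 σ`,
`std|G| = 0.4469 σ` — the Rayleigh closed form gives 0.8510/0.4448, and the
Monte-Carlo check in the test suite agrees within 2%. The 3D constant is
fixed by requiring that in the flat-slab limit (f → 0) the anisotropy-scaled
3D operator reduce exactly to the 2D one per slice, which makes the 3D
coefficient table consistent with the 2D constants by construction.

The 3D `(k_μ, k_σ)` table ships in `src/ilee/data/default_models.json`
(version and seed recorded there), built by measuring the scaled 3D gradient
of iid normal noise on the native lattice for f ∈ [0.1, 1.0]; the pipeline
computes the gradient before any z-interpolation, so iid native-lattice
noise is the coherent background model. Values are interpolated linearly in
f; outside the table range the nearest entry is used with a warning.

The `K2` model coefficients in the same file were refit with the package's
own `fit_k2_model` on a corpus of synthetic tube scenes of graded radius
(1.5–10 px): for each sample the single-K segmentation is swept over a log
grid and the K at which the mean deviation rate of the top-5%-DT ground-truth
pixels equals −0.2 (deliberate 20% under-coverage of the thickest bundles,
compensated by the union with the K1 pass) is interpolated; `log10 K*` is
then regressed on the Niblack thickness statistic. Corpus and seeds are in
the model file's provenance block.

## Mask lattices and index conventions

- Occupancy: native mask (2D), native-voxel mask (3D).
- Skeleton-borne indices: the 3×-oversampled mask in 2D (lengths and
  diameters divided by 3 to native px), the cubic-voxel mask in 3D (its
  voxel edge equals the native x/y pixel, so graph lengths are already in
  native units). 2D length uses the neighbour kernel (orthogonal step
  contributes 1/2 per pixel, diagonal √2/2); 3D length sums Euclidean branch
  lengths of the skeleton graph, since z-cavities make the 2D kernel
  inapplicable.
- Diameters: `TDT = 4·mean(DT over positive pixels)`, `SDT = 2·mean(DT at
  skeleton pixels)`. In 3D these are computed on the cubic mask by default:
  3×/f oversampling of a stack inflates the voxel count ~100× for a
  sub-pixel gain; the oversampled path exists (`compute_oversampled_3d`).
- Branching: a branch qualifies if at least one endpoint node has degree
  ≥ 3 (junction); adjacent junction pixels are merged into one node.
- Local anisotropy: branches are cut into 5-px chords; each contributes
  `w·g gᵀ` (w = chord length, g = unit direction) to the tensor of every
  probe ball containing its midpoint; the index is the length-weighted mean
  over probes of `λ_max − λ_min`. 1 = parallel, 0 = isotropic. The
  image-level mean weights each probe by its chord length (a raw-mean
  switch would be trivial to add; length weighting avoids sparsely covered
  probes dominating).

The skeleton graph itself (nodes, branches, Euclidean lengths, components)
is extracted in-package from the Lee-thinned mask under full connectivity;
isolated cycles are traced as single closed branches.

## The simulator

`synth_scene` rasterises smooth random tubes (unit-step curves with small
angular perturbations, reflected at the boundary) and records exact ground
truth: mask, centerline skeleton, per-filament length, component count, and
radius. Defaults emulate a confocal-scale field: a 64×256×256 lattice of
isotropic 0.132 µm voxels, six filaments of length 80–200 px, tube radii
1.5–4 px, and 12-bit reference brightnesses 800–3500 — the density and
thickness range of a moderately sparse actin network.

`generate_artificial_image` sums three brightness fractions:

- **actin** — every mask voxel finds its nearest skeleton voxel (reference
  `P_R`, distance `D_R`); the skeleton's clearance to background (`D_R2N`)
  normalises it to the relative eccentric distance `D_rlt = D_R/D_R2N`; the
  voxel's value is the reference brightness times a normal draw with mean
  `μ̂(D_rlt)` (1 below 0.2, `−0.647 D² + 0.226 D + 0.989` up to 1.4) and SD
  `σ̂(D_rlt) = −0.562 D² + 0.778 D + 0.065`; voxels beyond `D_rlt = 1.4`
  carry no actin signal. Nearest-voxel ties resolve lexicographically.
- **ground noise** — voxels belonging to a *real* base image's coarse
  background are perturbed by a `2^k` fold change (`k ~ N(0, 0.25²)`) and
  re-smoothed with the anisotropy-scaled Gaussian (reproduction mode); all
  other voxels draw iid from a Burr-XII fit. In the default self-contained
  mode no base image exists, so every ground-noise voxel takes the Burr-XII
  branch — iid right-skewed draws, which is what raw confocal sensor noise
  looks like. The shipped Burr parameters (c = 9.26, d = 0.635, loc = 0.08,
  scale = 83.6; mean ≈ 94, SD ≈ 25 in 12-bit units) were fitted once on
  bootstrap simulator output.
- **diffraction** — out-of-focus glow around the filaments. In reproduction
  mode the region between the coarse background and the actin is refilled
  iid from an exponential fit. In self-contained mode the halo is the smooth
  field `0.5 · ref(P_R) · exp(−d/1.0 px)` (d = distance to the mask):
  out-of-focus light is spatially smooth and decays on the PSF scale, so an
  iid refill of a self-defined ring would create brightness steps and
  internal gradient texture that no real halo has — artefacts the edge
  detector would then (correctly) segment. The amplitude 0.5 makes the halo
  continuous with the actin profile at the mask boundary (`μ̂(1) ≈ 0.57`).

Fractions are summed, clamped to [0, 4095], and the range is linearly
aligned to 12 bits (disable with `align_range=False` to inspect fractions).

What the generator does **not** emulate: optical PSF anisotropy along z,
depth-dependent attenuation, shot-noise/intensity coupling, multi-layer
backgrounds from out-of-focus cells, and real filament network topology
(bundles splitting and merging). Passing the end-to-end recovery tests
therefore shows that the pipeline is internally coherent on controlled
scenes of realistic geometry and noise statistics — not that its accuracy on
any particular real corpus equals the measured numbers.

## Evaluation conventions

Match/FP/FN rates are normalised by the ground-truth positive count. The
slim index of a segment is skeleton length over perimeter, with perimeter
counted as boundary pixel *faces* adjacent to background (a 1×20 run scores
19/42 ≈ 0.45); an FP segment 8-adjacent to matched pixels is actin-like only
if merging it raises both the slim index and the skeleton length of its host
segment. The noise sweep adds `N(0, σ²)` (clamped to the dynamic range) with
seeds derived per (σ, replicate); σ = 0 adds exactly zero noise, so those
runs are bit-identical to the noiseless analysis. The end-to-end recovery
checks use two 64×256×256 scenes and summarise "captured" structure as
matched data points over ground-truth voxels and as the skeleton length of
the matched set — sizes chosen so the full suite runs on one CPU core in a
few minutes.

## Numerical details

- All convolutions use reflection boundaries.
- Mask resampling interpolates the {0,1} float field and re-binarises at
  0.5; the segmentation path instead interpolates the *signed difference
  image* and thresholds at 0, preserving sub-pixel boundary placement.
- Resampled lattice lengths round half-away-from-zero (logged).
- NNES peak ties break to the smallest threshold.
- `σ_cbg = 0` (noiseless image) short-circuits `g_thres = 0` with a warning.
- The diagonal interpolation weights of the SDF are kept at the calibrated
  3-decimal values 0.293/0.707 rather than 1±1/√2 at full precision, so that
  worked values match the published constants digit for digit.
- `μ̂` is discontinuous by 0.0083 at `D_rlt = 0.2` (a property of the
  calibrated coefficients, tolerated as printed).

## Limitations

- **Structure-free images.** On pure noise with no filaments at all, the few
  gradient-tail pixels that exceed `g_thres` anchor the surface at the noise
  mean and the binarisation bisects the background (unless the selection is
  empty, in which case the output is correctly empty). ILEE presumes the
  image contains real edges; blank-field controls should be screened out
  before analysis rather than fed to the pipeline.
- The 2D-mode indices inherit projection artefacts: overlapping filaments
  merge, z-extent is lost, and digital skeleton lengths overestimate oblique
  segments by up to ~8% (8-connected chain-code bias).
- `K2` is a batch property; splitting a batch changes `K2` and therefore
  the indices. The manifest records the batch value to keep this auditable.
- The shipped regression constants were calibrated against confocal imagery
  with ~12-bit dynamic range and background noise SD of tens of gray levels;
  strongly different acquisition regimes warrant refitting via
  `fit_k2_model` / `build_ks_table` (`ilee fit-models`).
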