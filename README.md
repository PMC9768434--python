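# ilee — unguided segmentation and quantification of cytoskeletal images

Quantitative cytoskeleton biology needs a segmentation step that does not
depend on a human choosing a threshold: manual global thresholding (MGT) is
operator-biased and unstable across samples, while classical automatic
thresholds (Otsu, Li, Niblack, ...) either miss faint filaments or flood the
image with block noise. This package implements **ILEE** (Implicit Laplacian
of Enhanced Edge), an adaptive local-thresholding algorithm for 2D images and
3D confocal z-stacks of fluorescently labelled filament networks (plant
actin, stress fibers, and similar), together with a 12-index quantification
suite, a synthetic actin-image simulator with exact ground truth, and an
evaluation harness.

## The algorithm

Given a single-channel stack `I` (z-projected for 2D mode), ILEE proceeds:

1. **Edge enhancement.** A significant-difference filter replaces isolated
   single-pixel outliers by the mean of their surround (orthogonal
   neighbours plus diagonal values interpolated to unit distance,
   `0.293·center + 0.707·diagonal`), then a 3×3(×3) Gaussian (σ = 0.5)
   smooths the result into `I_pre`. In 3D the kernel is re-weighted for the
   voxel anisotropy `f = u_xy / u_z`.
2. **Background statistics without guidance.** Non-connected negative
   element scanning (NNES) counts sub-threshold elements at every gray
   level; the count peaks at the ground-noise mode `x_peak`. Regression
   models map `x_peak` to a coarse background threshold `t_cbg`
   (`1.163·x_peak + 101.68` in 2D; `7.334·x_peak` in 3D; an enhanced model
   `22.1408·p^1.004·w^0.481` uses the 80%-of-peak width `w`), and the
   standard deviation `σ_cbg` of the coarse background fixes a global
   gradient threshold

   `g_thres = k_μ σ_cbg + (k_coef σ_cbg)(k_σ σ_cbg)`

   with calibrated constants (2D: `k_μ = 0.8542`, `k_σ = 0.4469`,
   `k_coef = 0.040018`; 3D: anisotropy-dependent `k_μ, k_σ` from a shipped
   Monte-Carlo table, `k_coef = 0.040519`).
3. **Edge-constrained implicit Laplacian smoothing.** Pixels whose Scharr
   gradient magnitude exceeds `g_thres` anchor the sparse SPD system
   `(S + K L) x = S I_pre`, whose solution `x` is a threshold *surface*
   interpolating the filament edges. A small `K1 = 2.5` preserves thin and
   faint filaments; a larger `K2`, estimated per batch from a Niblack
   distance-transform thickness statistic, covers thick bundles. The binary
   mask is the union of the two binarisations of `I_pre − x` (after removal
   of sub-3-pixel elements), produced on the native, cubic-voxel, and
   3×-oversampled lattices.
4. **Indices.** Occupancy, linear density, skewness, CV, two
   distance-transform diameters (TDT/SDT), connected elements, segment
   density, branch/node counts, static branching activity, and local
   anisotropy of the filament alignment tensor — computed from the masks,
   the raw intensities, and an in-package skeleton graph.

## Worked example

Generate two artificial stacks with known ground truth and analyse them in
3D mode:

```bash
ilee simulate --out demo/scenes --n 2 --seed 7 --shape 24,160,160 --filaments 5
ilee analyze --mode 3d --input 'demo/scenes/scene_*[0-9].tif' --out demo/run
```

`demo/run/indices.csv` (first columns):

```
image,occupancy,linear_density,skewness,cv,diameter_tdt,diameter_sdt,total_connected_element
scene_000,0.027931,0.0010747,0.46605,0.59375,5.2755,3.3135,3.0
scene_001,0.030085,0.0008663,0.16845,0.38287,5.2389,3.2113,1.0
```

The ground-truth sidecars written by `simulate` say scene_000 has occupancy
0.02795, mean tube diameter 5.28 px, and 3 connected components — the
pipeline reports 0.02793, a TDT diameter of 5.28 px, and 3 elements, without
any user-supplied threshold. `demo/run/manifest.json` records the resolved
configuration, the model-file version, and the batch-universal `K2` (3.02
here) so that any run can be reproduced exactly.

The library API mirrors the CLI: `ilee.run_ilee(grid, mode="3d")` returns the
masks and all intermediates, `ilee.compute_indices(...)` the index report,
and `ilee.synth_scene` / `ilee.generate_artificial_image` the simulator.

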