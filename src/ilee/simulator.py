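"""Synthetic inputs with exact ground truth.

Two generators:

* :func:`synth_scene` — parametric filament scenes (random smooth tubes on a
  lattice) whose mask, skeleton, length, and component count are known by
  construction. These drive unit tests and end-to-end recovery checks.
* :func:`generate_artificial_image` — the statistical 3D artificial actin
  image model. An image is the sum of three brightness fractions: an actin
  fraction whose relative brightness decays with the relative eccentric
  distance ``D_rlt`` (distance to the skeleton normalised by the skeleton's
  clearance to background) through calibrated piecewise polynomials; a
  ground-noise fraction (coarse-background voxels perturbed by a lognormal
  fold change ``2^k, k ~ N(0, 0.25^2)`` and re-smoothed, other non-actin
  voxels drawn from a Burr-XII fit); and a diffraction fraction (exponential
  draws in the bright shell around filaments). Values are clamped to the
  12-bit range [0, 4095].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, stats

from .core_io import BinaryMask, VoxelGeometry, VoxelGrid
from .preprocess import gaussian_kernel, scaling_operator

logger = logging.getLogger("ilee")

CLAMP_MAX = 4095.0

#: relative-brightness mean: 1 up to D_rlt = 0.2, then a calibrated quadratic
MU_POLY = (-0.647, 0.226, 0.989)
MU_FLAT_BELOW = 0.2
#: relative-brightness STD quadratic, valid on [0, 1.4]
SIGMA_POLY = (-0.562, 0.778, 0.065)
#: beyond this relative eccentric distance a voxel carries no actin signal
D_RLT_CUTOFF = 1.4


def eval_relative_brightness(d_rlt: float | np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(mu, sigma) of the relative brightness at relative eccentric distance
    ``d_rlt``; NaN beyond the no-actin cutoff 1.4. Negative input rejected."""
    d = np.asarray(d_rlt, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("relative eccentric distance must be >= 0")
    mu = np.where(d <= MU_FLAT_BELOW, 1.0, np.polyval(MU_POLY, d))
    sigma = np.polyval(SIGMA_POLY, d)
    mu = np.where(d > D_RLT_CUTOFF, np.nan, mu)
    sigma = np.where(d > D_RLT_CUTOFF, np.nan, sigma)
    return mu, sigma


@dataclass
class ActinSimulationModel:
    """Distribution parameters of the three-fraction image model."""

    # Burr-XII / exponential defaults were fitted once on bootstrap simulator
    # output (see the shipped model file's provenance block)
    burr_c: float = 9.2553
    burr_d: float = 0.6352
    burr_loc: float = 0.0811
    burr_scale: float = 83.556
    exp_loc: float = 528.86
    exp_scale: float = 210.26
    cbg_fold_sd: float = 0.25
    clamp: Tuple[float, float] = (0.0, CLAMP_MAX)
    mu_poly: Tuple[float, float, float] = MU_POLY
    sigma_poly: Tuple[float, float, float] = SIGMA_POLY
    provenance: Dict[str, object] = field(default_factory=dict)

    def burr(self):
        return stats.burr12(self.burr_c, self.burr_d, loc=self.burr_loc, scale=self.burr_scale)

    def expon(self):
        return stats.expon(loc=self.exp_loc, scale=self.exp_scale)


# ---------------------------------------------------------------------------
# Parametric scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Recipe for a random filament scene; deterministic given the seed.

    Defaults emulate a confocal-scale field: a 64x256x256 voxel lattice with
    isotropic 0.132 µm voxels, a handful of smooth filaments 80-200 px long
    with tube radii 1.5-4 px and 12-bit brightnesses.
    """

    shape: Tuple[int, ...] = (64, 256, 256)
    u_xy: float = 0.132
    u_z: Optional[float] = 0.132
    n_filaments: int = 6
    length_range: Tuple[float, float] = (80.0, 200.0)
    radius_range: Tuple[float, float] = (1.5, 4.0)
    brightness_range: Tuple[float, float] = (800.0, 3500.0)
    curvature: float = 0.15  # SD of the per-step direction perturbation (rad)
    bit_depth: int = 12
    seed: int = 0

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def geometry(self) -> VoxelGeometry:
        return VoxelGeometry(u_xy=self.u_xy, u_z=self.u_z if self.ndim == 3 else None)


@dataclass
class Scene:
    """A rasterised scene with its exact ground truth."""

    spec: SceneSpec
    skeleton: np.ndarray  # bool
    mask: np.ndarray  # bool
    brightness: np.ndarray  # per-skeleton-voxel reference brightness
    truth: Dict[str, float]
    centerlines: List[np.ndarray] = field(default_factory=list)

    @property
    def geometry(self) -> VoxelGeometry:
        return self.spec.geometry

    def skeleton_mask(self) -> BinaryMask:
        return BinaryMask(values=self.skeleton, geometry=self.geometry)

    def filament_mask(self) -> BinaryMask:
        return BinaryMask(values=self.mask, geometry=self.geometry)


def _random_unit(rng: np.random.Generator, ndim: int) -> np.ndarray:
    v = rng.normal(size=ndim)
    return v / np.linalg.norm(v)


def _smooth_curve(
    rng: np.random.Generator, shape: Tuple[int, ...], length: float, curvature: float
) -> np.ndarray:
    """Unit-step random curve with small direction perturbations, reflected at
    the lattice boundary."""
    ndim = len(shape)
    margin = 2.0
    pos = np.array([rng.uniform(margin, s - 1 - margin) for s in shape])
    d = _random_unit(rng, ndim)
    pts = [pos.copy()]
    for _ in range(int(length)):
        d = d + curvature * rng.normal(size=ndim)
        d /= np.linalg.norm(d)
        pos = pos + d
        for ax in range(ndim):
            if pos[ax] < margin or pos[ax] > shape[ax] - 1 - margin:
                d[ax] = -d[ax]
                pos[ax] = np.clip(pos[ax], margin, shape[ax] - 1 - margin)
        pts.append(pos.copy())
    return np.array(pts)


def _rasterize(points: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Round a polyline to lattice voxels, deduplicating consecutive repeats."""
    vox = np.rint(points).astype(int)
    vox = np.clip(vox, 0, np.array(shape) - 1)
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
    return vox[keep]


def _polyline_length(vox: np.ndarray) -> float:
    if len(vox) < 2:
        return 0.0
    return float(np.sqrt(((vox[1:] - vox[:-1]) ** 2).sum(axis=1)).sum())


def synth_scene(spec: SceneSpec) -> Scene:
    """Rasterise random smooth tubes and compute their ground truth."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    skeleton = np.zeros(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    brightness = np.zeros(shape, dtype=np.float64)
    centerlines: List[np.ndarray] = []
    total_length = 0.0
    radii = []
    for _ in range(spec.n_filaments):
        length = rng.uniform(*spec.length_range)
        radius = rng.uniform(*spec.radius_range)
        bright = rng.uniform(*spec.brightness_range)
        pts = _smooth_curve(rng, shape, length, spec.curvature)
        vox = _rasterize(pts, shape)
        centerlines.append(vox)
        total_length += _polyline_length(vox)
        radii.append(radius)
        line = np.zeros(shape, dtype=bool)
        line[tuple(vox.T)] = True
        dist = ndimage.distance_transform_edt(~line)
        mask |= dist <= radius
        skeleton |= line
        brightness[tuple(vox.T)] = np.maximum(brightness[tuple(vox.T)], bright)
    structure = ndimage.generate_binary_structure(len(shape), len(shape))
    _, n_comp = ndimage.label(mask, structure=structure)
    truth = {
        "occupancy": float(mask.mean()),
        "total_length": total_length,
        "n_components": float(n_comp),
        "n_filaments": float(spec.n_filaments),
        "mean_radius": float(np.mean(radii)) if radii else math.nan,
        "mean_diameter": float(2 * np.mean(radii)) if radii else math.nan,
    }
    return Scene(
        spec=spec,
        skeleton=skeleton,
        mask=mask,
        brightness=brightness,
        truth=truth,
        centerlines=centerlines,
    )


# ---------------------------------------------------------------------------
# Artificial image generation
# ---------------------------------------------------------------------------


def relative_eccentric_distance(
    mask: np.ndarray, skeleton: np.ndarray
) -> Tuple[np.ndarray, Tuple[np.ndarray, ...], np.ndarray]:
    """(D_rlt, reference-voxel indices P_R, D_R) for every voxel.

    ``D_R`` is the distance to the nearest skeleton voxel, ``D_R2N`` the
    distance from that reference voxel to the nearest non-actin voxel;
    ``D_rlt = D_R / D_R2N`` (0 where the denominator is 0). Nearest-voxel
    ties resolve to the lexicographically smallest coordinate (the order the
    feature transform visits them).
    """
    d_r, idx = ndimage.distance_transform_edt(~skeleton, return_indices=True)
    p_r = tuple(idx)
    clearance = ndimage.distance_transform_edt(mask)  # distance to background
    d_r2n = clearance[p_r]
    with np.errstate(divide="ignore", invalid="ignore"):
        d_rlt = np.where(d_r2n > 0, d_r / d_r2n, 0.0)
    return d_rlt, p_r, d_r


def actin_fraction(
    scene: Scene, model: ActinSimulationModel, rng: np.random.Generator
) -> np.ndarray:
    """The filament brightness fraction of the artificial image."""
    d_rlt, p_r, _ = relative_eccentric_distance(scene.mask, scene.skeleton)
    mu = np.where(d_rlt <= MU_FLAT_BELOW, 1.0, np.polyval(model.mu_poly, d_rlt))
    sigma = np.polyval(model.sigma_poly, np.minimum(d_rlt, D_RLT_CUTOFF))
    ref = scene.brightness[p_r]
    noise = rng.normal(size=scene.mask.shape)
    vals = ref * (mu + np.clip(sigma, 0.0, None) * noise)
    vals[~scene.mask] = 0.0
    vals[d_rlt > D_RLT_CUTOFF] = 0.0
    return np.clip(vals, *model.clamp)


def ground_noise_fraction(
    scene: Scene,
    model: ActinSimulationModel,
    rng: np.random.Generator,
    base: np.ndarray,
    coarse_bg: np.ndarray,
) -> np.ndarray:
    """Fold-change-perturbed and re-smoothed coarse background; Burr-XII draws
    elsewhere."""
    k = rng.normal(0.0, model.cbg_fold_sd, size=base.shape)
    perturbed = np.where(coarse_bg, base * 2.0**k, 0.0)
    if base.ndim == 3:
        kern = gaussian_kernel(0.5, 1, 3) * scaling_operator(scene.geometry.f)
        kern /= kern.sum()
    else:
        kern = gaussian_kernel(0.5, 1, 2)
    smoothed = ndimage.convolve(perturbed, kern, mode="reflect")
    burr_vals = model.burr().rvs(size=base.shape, random_state=rng)
    out = np.where(coarse_bg, smoothed, burr_vals)
    return np.clip(out, *model.clamp)


def diffraction_fraction(
    scene: Scene,
    model: ActinSimulationModel,
    rng: np.random.Generator,
    actin: np.ndarray,
    coarse_bg: np.ndarray,
) -> np.ndarray:
    """Exponential draws on voxels that are neither coarse background nor actin
    (region refill, used when reproducing from a real frame)."""
    region = (~coarse_bg) & (actin == 0)
    out = np.zeros_like(actin)
    if region.any():
        out[region] = model.expon().rvs(size=int(region.sum()), random_state=rng)
    return np.clip(out, *model.clamp)


def diffraction_halo(
    scene: Scene,
    model: ActinSimulationModel,
    actin: np.ndarray,
    amplitude: float = 0.5,
    decay: float = 1.0,
    floor: float = 1.0,
) -> np.ndarray:
    """Smooth out-of-focus glow for self-contained scenes.

    Out-of-focus light decays continuously away from the filament, so the halo
    is ``amplitude * ref_brightness * exp(-d / decay)`` (d = distance to the
    filament mask in voxels, decay on the PSF scale), truncated below
    ``floor``. Its value distribution is exponential-family by construction,
    and — unlike an iid refill of a fixed ring — it merges into the ground
    noise without a brightness step, as real confocal halos do.
    """
    d = ndimage.distance_transform_edt(~scene.mask)
    _, p_r, _ = relative_eccentric_distance(scene.mask, scene.skeleton)
    ref = scene.brightness[p_r]
    halo = amplitude * ref * np.exp(-d / decay)
    halo[scene.mask] = 0.0
    halo[actin > 0] = 0.0
    halo[halo < floor] = 0.0
    return np.clip(halo, *model.clamp)


def generate_artificial_image(
    scene: Scene,
    model: Optional[ActinSimulationModel] = None,
    seed: int = 0,
    shell_width: int = 3,
    align_range: bool = True,
    base: Optional[np.ndarray] = None,
) -> Tuple[VoxelGrid, BinaryMask, Dict[str, float]]:
    """Sum the three brightness fractions over a scene frame.

    The ground-noise rule distinguishes voxels that belong to a real image's
    coarse background (perturb by a ``2^k`` fold change, then re-smooth) from
    all others (draw from the Burr-XII fit). In reproduction mode, pass the
    real stack as ``base`` and its coarse background is perturbed; in the
    default self-contained mode there is no base image, so every ground-noise
    voxel takes the Burr-XII branch — iid right-skewed draws, which is what
    raw confocal sensor noise looks like. The ``shell_width``-voxel dilation
    ring around the filament mask stands in for the out-of-focus diffraction
    region of a real stack. After summation the range is linearly aligned to
    [0, 4095] (disable with ``align_range=False`` to inspect raw fractions).
    """
    if not scene.skeleton.any():
        raise ValueError("frame without a skeleton cannot be simulated")
    model = model or ActinSimulationModel()
    rng = np.random.default_rng(seed)
    actin = actin_fraction(scene, model, rng)
    if base is not None:
        # reproduction mode: perturb the provided stack's coarse background,
        # Burr-XII elsewhere, iid exponential refill of the diffraction ring
        shell = ndimage.binary_dilation(scene.mask, iterations=shell_width)
        coarse_bg = ~shell
        gn = ground_noise_fraction(scene, model, rng, base, coarse_bg)
        dif = diffraction_fraction(scene, model, rng, actin, coarse_bg)
    else:
        # self-contained mode: no real background exists, so every
        # ground-noise voxel takes the Burr-XII branch; the diffraction glow
        # decays smoothly from the filament surface
        coarse_bg = np.zeros(scene.mask.shape, dtype=bool)
        gn = ground_noise_fraction(scene, model, rng, np.zeros(scene.mask.shape), coarse_bg)
        dif = diffraction_halo(scene, model, actin)
    total = np.clip(actin + gn + dif, 0.0, CLAMP_MAX)
    if align_range:
        lo, hi = float(total.min()), float(total.max())
        if hi > lo:
            total = (total - lo) / (hi - lo) * CLAMP_MAX
    grid = VoxelGrid(values=total, geometry=scene.geometry, bit_depth=scene.spec.bit_depth)
    return grid, scene.filament_mask(), dict(scene.truth)


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------


def bin_weights(counts: np.ndarray) -> np.ndarray:
    """Regression weights log10(N) per D_rlt bin (bins with N < 2 drop out)."""
    counts = np.asarray(counts, dtype=np.float64)
    w = np.where(counts >= 2, np.log10(np.maximum(counts, 2)), 0.0)
    return w


def _weighted_quadfit(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> Tuple[float, float, float]:
    keep = w > 0
    if keep.sum() < 3:
        raise ValueError("need at least 3 weighted bins for a quadratic fit")
    c = np.polyfit(x[keep], y[keep], 2, w=np.sqrt(w[keep]))
    return tuple(float(v) for v in c)


def fit_relative_brightness(
    d_rlt: np.ndarray,
    i_rlt: np.ndarray,
    bin_width: float = 0.05,
    fit_range: Tuple[float, float] = (MU_FLAT_BELOW, 1.0),
) -> Tuple[Tuple[float, float, float], Tuple[float, float, float], np.ndarray]:
    """Weighted quadratic fits of the per-bin mean and STD of the relative
    brightness over ``fit_range`` (only D_rlt <= 1 voxels inform the model)."""
    d = np.asarray(d_rlt).ravel()
    i = np.asarray(i_rlt).ravel()
    keep = (d > fit_range[0]) & (d <= fit_range[1]) & np.isfinite(i)
    d, i = d[keep], i[keep]
    bins = np.floor(d / bin_width).astype(int)
    uniq = np.unique(bins)
    centers, means, stds, counts = [], [], [], []
    for b in uniq:
        sel = bins == b
        n = int(sel.sum())
        if n < 2:
            continue
        centers.append((b + 0.5) * bin_width)
        means.append(float(i[sel].mean()))
        stds.append(float(i[sel].std()))
        counts.append(n)
    centers = np.array(centers)
    counts = np.array(counts)
    w = bin_weights(counts)
    mu_c = _weighted_quadfit(centers, np.array(means), w)
    sigma_c = _weighted_quadfit(centers, np.array(stds), w)
    return mu_c, sigma_c, counts


def fit_simulation_model(
    images: Sequence[VoxelGrid],
    masks: Sequence[np.ndarray],
    skeletons: Sequence[np.ndarray],
    t_cbgs: Sequence[float],
) -> ActinSimulationModel:
    """Refit the three-fraction model from (image, mask, skeleton) triples.

    The relative-brightness polynomials use only voxels with D_rlt <= 1,
    weighted by log10 of the per-bin voxel count; the Burr-XII fit uses
    coarse-background voxels, the exponential fit the remaining non-actin
    voxels.
    """
    all_d, all_i, bg_vals, dif_vals = [], [], [], []
    for grid, mask, skel, t_cbg in zip(images, masks, skeletons, t_cbgs):
        mask = np.asarray(mask, dtype=bool)
        skel = np.asarray(skel, dtype=bool)
        if not skel.any():
            continue
        d_rlt, p_r, _ = relative_eccentric_distance(mask, skel)
        v = grid.values
        ref = v[p_r]
        with np.errstate(divide="ignore", invalid="ignore"):
            i_rlt = np.where(ref > 0, v / ref, 0.0)
        sel = mask & (d_rlt <= 1.0)
        all_d.append(d_rlt[sel])
        all_i.append(i_rlt[sel])
        cbg = v <= t_cbg
        bg_vals.append(v[cbg])
        dif_region = (~cbg) & (~mask)
        dif_vals.append(v[dif_region])
    if not all_d:
        raise ValueError("no usable training voxels")
    mu_c, sigma_c, _ = fit_relative_brightness(np.concatenate(all_d), np.concatenate(all_i))
    bg = np.concatenate(bg_vals)
    c, dshape, loc, scale = stats.burr12.fit(bg, 5.0, 0.6)
    dif = np.concatenate(dif_vals) if dif_vals else np.array([])
    if dif.size >= 10:
        eloc, escale = stats.expon.fit(dif)
    else:
        eloc, escale = 0.0, 200.0
        logger.warning("too few diffraction voxels; exponential defaults kept")
    return ActinSimulationModel(
        burr_c=float(c),
        burr_d=float(dshape),
        burr_loc=float(loc),
        burr_scale=float(scale),
        exp_loc=float(eloc),
        exp_scale=float(escale),
        mu_poly=mu_c,
        sigma_poly=sigma_c,
        provenance={"n_images": len(images)},
    )
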