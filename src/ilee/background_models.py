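"""Coarse-background detection (NNES) and global-gradient-threshold models.

NNES — non-connected negative element scanning — counts, for every scanned
grayscale threshold ``x``, the non-connected elements of the sub-threshold
set ``{pixel <= x}`` of the flattened image (maximal 1D runs). For
normal-like ground noise the count peaks when ``x`` sits at the noise mode
(adjacent pixels disagree most often there), which makes the peak position
``x_peak`` a robust feature of the background even when the brightness
histogram itself is turbulent. Regression models then map ``x_peak`` (and, in
the enhanced 3D model, the 80%-of-peak width ``w``) to a coarse global
threshold ``t_cbg``; the standard deviation of the coarse background,
``sigma_cbg``, finally drives the gradient-threshold model

    g_thres = k_mu * sigma_cbg + (k_coef * sigma_cbg) * (k_sigma * sigma_cbg)

with calibrated 2D constants and, in 3D, anisotropy-dependent ``(k_mu,
k_sigma)`` from a Monte-Carlo table shipped with the package.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, Literal, Optional, Sequence, Tuple

import numpy as np

from .core_io import VoxelGeometry, VoxelGrid
from .gradient_and_edges import scharr_magnitude

logger = logging.getLogger("ilee")

Mode = Literal["2d", "3d", "3d_enhanced"]


# ---------------------------------------------------------------------------
# NNES
# ---------------------------------------------------------------------------


@dataclass
class NNESCurve:
    """NNE counts over scanned thresholds, with peak position and 80% width."""

    thresholds: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.thresholds.shape != self.counts.shape or self.thresholds.size == 0:
            raise ValueError("thresholds and counts must be equal-length, nonempty")

    @property
    def x_peak(self) -> float:
        # ties broken to the smallest threshold (argmax returns first max)
        return float(self.thresholds[int(np.argmax(self.counts))])

    @property
    def peak_count(self) -> int:
        return int(self.counts.max())

    @property
    def w(self) -> float:
        """Distance between the outermost thresholds with >= 80% of peak count."""
        high = np.nonzero(self.counts >= 0.8 * self.peak_count)[0]
        return float(self.thresholds[high[-1]] - self.thresholds[high[0]])


def _count_nne(values: np.ndarray, x: float) -> int:
    """Count non-connected negative elements of the flattened image.

    Elements are maximal runs of sub-threshold pixels along image rows (the
    fastest axis of the flattened array; rows do not wrap). This is the
    counting rule under which the NNE curve of iid noise peaks exactly at the
    noise mean — the property the coarse-background models are built on: run
    density is p(1-p) for sub-threshold probability p, maximal at p = 1/2,
    i.e. at the median of the noise. Lattice component labeling instead peaks
    near the p = 0.27 quantile and would shift every downstream regression.
    """
    neg = values <= x
    if not neg.any():
        return 0
    starts = int(np.count_nonzero(neg[..., 0])) + int(
        np.count_nonzero(neg[..., 1:] & ~neg[..., :-1])
    )
    return starts


def nnes_scan(
    grid: VoxelGrid,
    step: float = 1.0,
    full_scan_limit: int = 512,
    coarse_points: int = 128,
) -> NNESCurve:
    """Scan NNE counts over integer-spaced grayscale thresholds.

    When the full integer scan would exceed ``full_scan_limit`` labelings, a
    coarse scan first brackets the peak and its 80% band, which is then
    re-scanned at the requested step. The curve always starts one step below
    the grid minimum so the zero-count baseline is present.
    """
    v = grid.values
    lo = math.floor(float(v.min())) - step
    hi = math.ceil(float(v.max()))
    n_full = int((hi - lo) / step) + 1
    if n_full <= full_scan_limit:
        thresholds = lo + step * np.arange(n_full)
    else:
        stride = (hi - lo) / (coarse_points - 1)
        coarse_t = lo + stride * np.arange(coarse_points)
        coarse_c = np.array([_count_nne(v, x) for x in coarse_t])
        peak = coarse_c.max()
        band = np.nonzero(coarse_c >= 0.8 * peak)[0]
        left = max(lo, coarse_t[band[0]] - stride)
        right = min(hi, coarse_t[band[-1]] + stride)
        n_fine = int((right - left) / step) + 1
        thresholds = left + step * np.arange(n_fine)
        logger.debug(
            "nnes_scan: refined band [%.1f, %.1f] (%d thresholds)", left, right, n_fine
        )
    counts = np.array([_count_nne(v, x) for x in thresholds])
    return NNESCurve(thresholds=thresholds, counts=counts)


# ---------------------------------------------------------------------------
# Coarse background
# ---------------------------------------------------------------------------


@dataclass
class CoarseBackground:
    """Pixels at or below ``t_cbg``, with their first two moments."""

    t_cbg: float
    mask: np.ndarray
    mu_cbg: float
    sigma_cbg: float


def coarse_background(grid: VoxelGrid, t_cbg: float) -> CoarseBackground:
    mask = grid.values <= t_cbg
    if mask.any():
        vals = grid.values[mask]
        mu, sigma = float(vals.mean()), float(vals.std())
    else:
        mu, sigma = float("nan"), 0.0
        logger.warning("coarse background empty at t_cbg=%.3f", t_cbg)
    return CoarseBackground(t_cbg=float(t_cbg), mask=mask, mu_cbg=mu, sigma_cbg=sigma)


# ---------------------------------------------------------------------------
# Shipped model constants
# ---------------------------------------------------------------------------


@dataclass
class ThresholdModels:
    """Regression constants for t_cbg, g_thres, the 3D k_s table, and K2.

    Defaults are the calibrated constants; the k_s table, the K2 estimation
    model, and the simulator noise fits ship in ``data/default_models.json``
    (versioned, swappable via :func:`load_models`).
    """

    # coarse background: t_cbg = slope*x_peak + intercept (2D), slope*x_peak (3D)
    cbg_2d_slope: float = 1.163
    cbg_2d_intercept: float = 101.68
    cbg_3d_slope: float = 7.334
    # enhanced 3D model: a * p^m * w^n
    cbg_3d_enh_a: float = 22.1408
    cbg_3d_enh_m: float = 1.004
    cbg_3d_enh_n: float = 0.481
    # gradient threshold model
    grad_2d_k_mu: float = 0.8542
    grad_2d_k_sigma: float = 0.4469
    grad_2d_k_coef: float = 0.040018
    grad_3d_k_coef: float = 0.040519
    # Monte-Carlo k_s table: anisotropy factor f -> (k_mu, k_sigma)
    ks_table: Dict[float, Tuple[float, float]] = field(default_factory=dict)
    # K2 estimation: log10(K2) = a + b * top5%-DT statistic
    k2_log10_a: float = 0.0
    k2_log10_b: float = 0.25
    # provenance of fitted entries
    version: str = "builtin"
    provenance: Dict[str, object] = field(default_factory=dict)


def load_models(path: Optional[str | Path] = None) -> ThresholdModels:
    """Load model constants from JSON (default: the shipped file)."""
    if path is None:
        text = resources.files("ilee").joinpath("data/default_models.json").read_text()
    else:
        text = Path(path).read_text()
    raw = json.loads(text)
    ks = {float(k): tuple(v) for k, v in raw.get("ks_table", {}).items()}
    kwargs = {k: v for k, v in raw.items() if k not in ("ks_table",)}
    return ThresholdModels(ks_table=ks, **kwargs)


_DEFAULT_MODELS: Optional[ThresholdModels] = None


def default_models() -> ThresholdModels:
    global _DEFAULT_MODELS
    if _DEFAULT_MODELS is None:
        _DEFAULT_MODELS = load_models()
    return _DEFAULT_MODELS


# ---------------------------------------------------------------------------
# Threshold models
# ---------------------------------------------------------------------------


def coarse_threshold(
    curve: NNESCurve, mode: Mode, models: Optional[ThresholdModels] = None
) -> float:
    """Map an NNES curve to the coarse global threshold ``t_cbg``."""
    models = models or default_models()
    p = curve.x_peak
    if mode == "2d":
        return models.cbg_2d_slope * p + models.cbg_2d_intercept
    if mode == "3d":
        return models.cbg_3d_slope * p
    if mode == "3d_enhanced":
        w = curve.w
        if not w > 0:
            raise ValueError("enhanced 3D coarse model requires peak width w > 0")
        return models.cbg_3d_enh_a * p**models.cbg_3d_enh_m * w**models.cbg_3d_enh_n
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_coarse_model(
    mode: Mode, x_peak: float, w: float = 1.0, models: Optional[ThresholdModels] = None
) -> float:
    """Evaluate the coarse-background regression directly from its inputs."""
    models = models or default_models()
    if mode == "2d":
        return models.cbg_2d_slope * x_peak + models.cbg_2d_intercept
    if mode == "3d":
        return models.cbg_3d_slope * x_peak
    if mode == "3d_enhanced":
        return models.cbg_3d_enh_a * x_peak**models.cbg_3d_enh_m * w**models.cbg_3d_enh_n
    raise ValueError(f"unknown mode {mode!r}")


def gradient_weight_coef(sigma_cbg: float, mode: Literal["2d", "3d"], models=None) -> float:
    """The sigma-dependent weighting coefficient k(sigma_cbg) of the g_thres model."""
    models = models or default_models()
    coef = models.grad_2d_k_coef if mode == "2d" else models.grad_3d_k_coef
    return coef * sigma_cbg


def noise_gradient_coefficients(
    mode: Literal["2d", "3d"],
    f: Optional[float] = None,
    models: Optional[ThresholdModels] = None,
) -> Tuple[float, float]:
    """(k_mu, k_sigma): proportionality of background-gradient mean/STD to sigma_cbg.

    2D returns the calibrated constants. 3D interpolates the shipped
    Monte-Carlo table over the anisotropy factor f; outside the simulated
    range the nearest entry is used with a warning.
    """
    models = models or default_models()
    if mode == "2d":
        return models.grad_2d_k_mu, models.grad_2d_k_sigma
    if f is None:
        raise ValueError("3D mode requires the anisotropy factor f")
    if not models.ks_table:
        raise ValueError("no k_s table available in the model file")
    fs = np.array(sorted(models.ks_table))
    kmu = np.array([models.ks_table[x][0] for x in fs])
    ksig = np.array([models.ks_table[x][1] for x in fs])
    if f < fs[0] or f > fs[-1]:
        warnings.warn(
            f"f={f:.3f} outside the simulated range [{fs[0]:.2f}, {fs[-1]:.2f}]; "
            "using the nearest table entry",
            stacklevel=2,
        )
        f = float(np.clip(f, fs[0], fs[-1]))
    return float(np.interp(f, fs, kmu)), float(np.interp(f, fs, ksig))


def estimate_gradient_threshold(
    cbg: CoarseBackground,
    mode: Literal["2d", "3d"],
    f: Optional[float] = None,
    models: Optional[ThresholdModels] = None,
) -> float:
    """g_thres = mu_G.cbg + k(sigma_cbg) * sigma_G.cbg."""
    models = models or default_models()
    sigma = cbg.sigma_cbg
    if sigma == 0:
        logger.warning("sigma_cbg = 0 (noiseless image); g_thres set to 0")
        return 0.0
    k_mu, k_sigma = noise_gradient_coefficients(mode, f=f, models=models)
    k = gradient_weight_coef(sigma, mode, models)
    return k_mu * sigma + k * (k_sigma * sigma)


# ---------------------------------------------------------------------------
# Monte-Carlo construction of the 3D k_s table
# ---------------------------------------------------------------------------


def build_ks_table(
    f_values: Sequence[float] = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2)),
    shape: Tuple[int, int, int] = (25, 256, 256),
    sigma: float = 30.0,
    mean: float = 90.0,
    seed: int = 20230711,
) -> Dict[float, Tuple[float, float]]:
    """Simulate iid normal background noise on the native lattice and measure
    the scaled 3D Scharr magnitude statistics for each anisotropy factor f.

    The gradient of real stacks is computed before any z interpolation, so
    the relevant background model is iid noise under the f-scaled kernels.
    """
    rng = np.random.default_rng(seed)
    noise = rng.normal(mean, sigma, size=shape)
    table: Dict[float, Tuple[float, float]] = {}
    for f in f_values:
        geom = VoxelGeometry(u_xy=1.0, u_z=1.0 / f)
        grid = VoxelGrid(values=noise, geometry=geom, bit_depth=16)
        g = scharr_magnitude(grid).values[1:-1, 1:-1, 1:-1]
        table[float(f)] = (float(g.mean() / sigma), float(g.std() / sigma))
    return table
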