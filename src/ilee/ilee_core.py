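"""The ILEE threshold surface.

Edge pixels (gradient magnitude above ``g_thres``) act as anchors whose
preprocessed intensities are interpolated across the whole lattice by an
edge-constrained implicit Laplacian system

    (S + K L) x = S i_pre

where ``S`` is the 0/1 diagonal selection operator, ``L`` the graph Laplacian
of the pixel lattice, and ``K`` the smoothing coefficient. Small ``K`` keeps
the threshold surface close to the anchors (thin and faint filaments are
preserved); large ``K`` flattens it toward a global mean (thick, bright
bundles are covered). The final segmentation is the elementwise union of a
low-``K`` (``K1``, default 2.5) and a high-``K`` (``K2``, estimated per
batch) binarisation.

Note on the system: the form ``(S + K L) x = S i_pre`` is the reading that
satisfies the constant-image fixed point (a constant image yields a constant
threshold surface for every K and selection) and both limits — ``x`` at the
anchors tends to their intensities as K -> 0+, and flattens as K -> inf. The
transposed form ``(L + K S) x = S i_pre`` satisfies neither and is available
only for forensic comparison (``system="LKS"``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, splu
from skimage.filters import threshold_niblack

from .background_models import (
    ThresholdModels,
    coarse_background,
    coarse_threshold,
    default_models,
    estimate_gradient_threshold,
    nnes_scan,
)
from .core_io import BinaryMask, VoxelGeometry, VoxelGrid, _resize_float, max_project
from .gradient_and_edges import EdgeSelection, scharr_magnitude, select_edges
from .preprocess import PreprocessParams, preprocess

logger = logging.getLogger("ilee")

LaplacianMode = Literal["2d4", "2d8", "3d6"]

SQRT2_HALF = math.sqrt(2.0) / 2.0


@dataclass
class ILEEParams:
    """Tunable parameters of the segmentation core."""

    k1: float = 2.5
    k2: Optional[float] = None  # estimated per batch when None
    use_single_k: bool = False  # 3D shortcut: one K instead of K1/K2
    single_k: Optional[float] = None
    connectivity_2d: int = 8
    oversample_factor: int = 3
    min_element_size: int = 3
    solver_rtol: float = 1e-8
    solver_maxiter: int = 50000
    interp_order: int = 3
    cbg_model_3d: Literal["3d", "3d_enhanced"] = "3d"
    #: 3x/f oversampling of the 3D difference image is memory-hungry and
    #: optional; cubic-lattice masks are always produced in 3D.
    compute_oversampled_3d: bool = False
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if self.k2 is not None and self.k2 < self.k1:
            raise ValueError("k2 must be >= k1")
        if self.min_element_size < 1:
            raise ValueError("min_element_size must be >= 1")
        if self.connectivity_2d not in (4, 8):
            raise ValueError("connectivity_2d must be 4 or 8")


# ---------------------------------------------------------------------------
# Laplacian construction
# ---------------------------------------------------------------------------

_OFFSETS: Dict[str, Tuple[Tuple[Tuple[int, ...], float], ...]] = {
    "2d4": (((0, 1), 1.0), ((1, 0), 1.0)),
    "2d8": (
        ((0, 1), 1.0),
        ((1, 0), 1.0),
        ((1, 1), SQRT2_HALF),
        ((1, -1), SQRT2_HALF),
    ),
    "3d6": (((0, 0, 1), 1.0), ((0, 1, 0), 1.0), ((1, 0, 0), 1.0)),
}


@lru_cache(maxsize=8)
def build_laplacian(shape: Tuple[int, ...], mode: LaplacianMode) -> sparse.csr_matrix:
    """Weighted graph Laplacian over the flattened pixel lattice.

    Interior weights: orthogonal 1, diagonal sqrt(2)/2 (2D 8-connectivity);
    at borders the diagonal equals the sum of the actually present neighbour
    weights, so every row sums to exactly zero.
    """
    if mode not in _OFFSETS:
        raise ValueError(f"unknown Laplacian mode {mode!r}")
    ndim = 2 if mode.startswith("2d") else 3
    if len(shape) != ndim:
        raise ValueError(f"mode {mode} expects {ndim}D shape, got {shape}")
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    rows: List[np.ndarray] = []
    cols: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    for offset, w in _OFFSETS[mode]:
        src = [slice(None)] * ndim
        dst = [slice(None)] * ndim
        for ax, d in enumerate(offset):
            if d == 1:
                src[ax] = slice(0, shape[ax] - 1)
                dst[ax] = slice(1, shape[ax])
            elif d == -1:
                src[ax] = slice(1, shape[ax])
                dst[ax] = slice(0, shape[ax] - 1)
        i = idx[tuple(src)].ravel()
        j = idx[tuple(dst)].ravel()
        rows.append(i)
        cols.append(j)
        vals.append(np.full(i.size, w))
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    # symmetric adjacency
    adj = sparse.coo_matrix(
        (np.concatenate([v, v]), (np.concatenate([r, c]), np.concatenate([c, r]))),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    return (sparse.diags(deg) - adj).tocsr()


def laplacian_mode_for(grid_ndim: int, params: ILEEParams) -> LaplacianMode:
    if grid_ndim == 3:
        return "3d6"
    return "2d8" if params.connectivity_2d == 8 else "2d4"


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


class SolverError(RuntimeError):
    def __init__(self, residual: float, rtol: float, iters: int):
        super().__init__(
            f"conjugate-gradient solver did not reach rtol={rtol:g} within "
            f"{iters} iterations (relative residual {residual:.3e})"
        )
        self.residual = residual


def solve_threshold_surface(
    i_pre: VoxelGrid,
    edges: EdgeSelection,
    k: float,
    params: Optional[ILEEParams] = None,
    system: Literal["SKL", "LKS"] = "SKL",
) -> VoxelGrid:
    """Solve the edge-constrained smoothing system for the threshold surface.

    With an empty selection the (connected) lattice has no anchor and the
    whole image is classified background: the surface is +inf everywhere.
    """
    params = params or ILEEParams()
    if k <= 0:
        raise ValueError("smoothing coefficient k must be positive")
    if edges.count == 0:
        logger.warning("empty edge selection: whole image classified background")
        out = VoxelGrid(
            values=np.zeros(i_pre.shape), geometry=i_pre.geometry, bit_depth=i_pre.bit_depth
        )
        # +inf marks the documented degenerate path (threshold above any value);
        # assigned after construction since raw grids must be finite
        out.values = np.full(i_pre.shape, np.inf)
        return out
    x = _solve_system(i_pre.values, edges.mask, float(k), params, system)
    return VoxelGrid(values=x, geometry=i_pre.geometry, bit_depth=i_pre.bit_depth)


def _prolongation(fine_shape: Tuple[int, ...]) -> Tuple[sparse.csr_matrix, Tuple[int, ...]]:
    """Piecewise-constant prolongation from a 2x-coarsened lattice (odd axis
    lengths round up; the trailing coarse cell then has fewer children)."""
    coarse_shape = tuple((s + 1) // 2 for s in fine_shape)
    nf = int(np.prod(fine_shape))
    fidx = np.arange(nf)
    coords = np.unravel_index(fidx, fine_shape)
    cidx = np.ravel_multi_index(tuple(c // 2 for c in coords), coarse_shape)
    P = sparse.coo_matrix(
        (np.ones(nf), (fidx, cidx)), shape=(nf, int(np.prod(coarse_shape)))
    ).tocsr()
    return P, coarse_shape


class _Multigrid:
    """Galerkin V-cycle preconditioner for the edge-constrained system.

    Coarse operators are P^T A P with piecewise-constant prolongation;
    smoothing is damped Jacobi and the coarsest level is factorised
    directly. With the selection clustered on filament edges the plain
    Jacobi-CG condition number is dominated by the long-range harmonic
    fill of anchor-free regions; the Galerkin hierarchy removes it
    (typically ~20 CG iterations at rtol 1e-8).
    """

    OMEGA = 0.8

    def __init__(self, A: sparse.csr_matrix, shape: Tuple[int, ...], min_n: int = 20_000):
        self.levels: List[Dict[str, object]] = []
        while True:
            d = A.diagonal()
            self.levels.append(
                {"A": A, "dinv": 1.0 / np.where(d > 0, d, 1.0), "shape": shape}
            )
            if np.prod(shape) <= min_n or min(shape) <= 4:
                break
            P, shape_c = _prolongation(shape)
            self.levels[-1]["P"] = P
            A = (P.T @ A @ P).tocsr()
            shape = shape_c
        bottom = self.levels[-1]
        A_b = bottom["A"]
        # tiny diagonal shift guards the (rare) all-unselected singular case
        bottom["lu"] = splu((A_b + 1e-12 * sparse.eye(A_b.shape[0])).tocsc())

    def vcycle(self, r: np.ndarray, li: int = 0) -> np.ndarray:
        lvl = self.levels[li]
        if "lu" in lvl:
            return lvl["lu"].solve(r)
        A, dinv, P = lvl["A"], lvl["dinv"], lvl["P"]
        x = self.OMEGA * dinv * r
        x = x + self.OMEGA * dinv * (r - A @ x)
        x = x + P @ self.vcycle(P.T @ (r - A @ x), li + 1)
        x = x + self.OMEGA * dinv * (r - A @ x)
        return x


def _solve_system(
    values: np.ndarray,
    sel_mask: np.ndarray,
    k: float,
    params: ILEEParams,
    system: str,
) -> np.ndarray:
    """Assemble and solve (S + kL) x = S v.

    2D lattices up to ~400k pixels go through a sparse direct factorisation;
    larger problems use conjugate gradients, preconditioned by a geometric
    multigrid V-cycle when the lattice is large enough to warrant the setup.
    """
    shape = values.shape
    mode = laplacian_mode_for(values.ndim, params)
    L = build_laplacian(shape, mode)
    sel = sel_mask.ravel().astype(np.float64)
    S = sparse.diags(sel)
    if system == "SKL":
        A = (S + k * L).tocsr()
    else:  # forensic: the printed transposed form
        A = (L + k * S).tocsr()
    b = sel * values.ravel()
    n = A.shape[0]
    if n <= 400_000 and values.ndim == 2:
        return splu(A.tocsc()).solve(b).reshape(shape)
    x0 = np.full(n, values[sel_mask].mean())
    if system == "SKL" and n > 1_000_000 and min(shape) > 8:
        M = sparse.linalg.LinearOperator(A.shape, matvec=_Multigrid(A, shape).vcycle)
    else:
        diag = A.diagonal()
        M = sparse.diags(1.0 / np.where(diag > 0, diag, 1.0))
    x, info = cg(A, b, x0=x0, rtol=params.solver_rtol, maxiter=params.solver_maxiter, M=M)
    if info != 0:
        res = float(np.linalg.norm(A @ x - b) / np.linalg.norm(b))
        raise SolverError(res, params.solver_rtol, params.solver_maxiter)
    return x.reshape(shape)


# ---------------------------------------------------------------------------
# Difference, denoising, binarisation
# ---------------------------------------------------------------------------


def difference_and_denoise(
    i_pre: VoxelGrid, i_thres: VoxelGrid, params: Optional[ILEEParams] = None
) -> np.ndarray:
    """``I_dif = I_pre - I_thres`` with tiny positive components suppressed.

    Positive connected components (orthogonal connectivity) smaller than
    ``min_element_size`` are reset to the mean of the negative difference
    values (0 when no negative pixel exists).
    """
    params = params or ILEEParams()
    if i_pre.shape != i_thres.shape:
        raise ValueError("shape mismatch between I_pre and I_thres")
    dif = i_pre.values - i_thres.values
    pos = dif > 0
    if not pos.any():
        return dif
    structure = ndimage.generate_binary_structure(dif.ndim, 1)
    labels, n = ndimage.label(pos, structure=structure)
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < params.min_element_size)[0]
    small = small[small > 0]
    if small.size:
        neg = dif[dif < 0]
        if neg.size:
            fill = float(neg.mean())
        else:
            fill = 0.0
            logger.warning("no negative difference pixels; small elements reset to 0")
        dif = dif.copy()
        dif[np.isin(labels, small)] = fill
    return dif


def binarize(
    i_dif_adj: np.ndarray,
    geometry: VoxelGeometry,
    params: Optional[ILEEParams] = None,
) -> Dict[str, BinaryMask]:
    """Native / cubic / oversampled masks from the adjusted difference image.

    Interpolation is applied to the float difference image *before*
    thresholding at zero, so sub-pixel boundary placement survives.
    """
    params = params or ILEEParams()
    ndim = i_dif_adj.ndim
    s = params.oversample_factor
    order = params.interp_order
    out: Dict[str, BinaryMask] = {}
    out["native"] = BinaryMask(values=i_dif_adj > 0, geometry=geometry, provenance="native")
    if ndim == 2:
        ny, nx = i_dif_adj.shape
        ovsp = _resize_float(i_dif_adj, (ny * s, nx * s), order) > 0
        out["oversampled"] = BinaryMask(
            values=ovsp,
            geometry=VoxelGeometry(u_xy=geometry.u_xy / s),
            provenance="oversampled",
            scale=(float(s), float(s)),
        )
        return out
    f = geometry.f
    nz, ny, nx = i_dif_adj.shape
    nz_cubic = max(1, int(math.floor(nz / f + 0.5)))
    cubic = _resize_float(i_dif_adj, (nz_cubic, ny, nx), order) > 0
    out["cubic"] = BinaryMask(
        values=cubic,
        geometry=VoxelGeometry(u_xy=geometry.u_xy, u_z=geometry.u_z * nz / nz_cubic),
        provenance="cubic",
        scale=(nz_cubic / nz, 1.0, 1.0),
    )
    if params.compute_oversampled_3d:
        shape_ov = (nz_cubic * s, ny * s, nx * s)
        ovsp = _resize_float(i_dif_adj, shape_ov, order) > 0
        out["oversampled"] = BinaryMask(
            values=ovsp,
            geometry=VoxelGeometry(u_xy=geometry.u_xy / s, u_z=geometry.u_z * nz / (nz_cubic * s)),
            provenance="oversampled",
            scale=(s * nz_cubic / nz, float(s), float(s)),
        )
    return out


# ---------------------------------------------------------------------------
# K2 estimation
# ---------------------------------------------------------------------------


@dataclass
class K2Model:
    """log10(K2) affine in the batch top-5% distance-transform statistic."""

    a: float
    b: float
    provenance: Dict[str, object] = field(default_factory=dict)

    def __call__(self, dt_stat: float) -> float:
        return 10.0 ** (self.a + self.b * dt_stat)

    @classmethod
    def from_models(cls, models: Optional[ThresholdModels] = None) -> "K2Model":
        models = models or default_models()
        return cls(a=models.k2_log10_a, b=models.k2_log10_b, provenance={"version": models.version})


def niblack_top_dt(grid: VoxelGrid, k: float = -0.36, top_fraction: float = 0.05) -> Optional[float]:
    """Per-image filament-thickness statistic: mean of the top 5% Euclidean
    distance-transform values of a Niblack-binarised maximum projection."""
    img = max_project(grid).values if grid.ndim == 3 else grid.values
    l = 0.5 * (img.shape[0] + img.shape[1])
    window = 2 * int(l / 25) + 1
    if window < 3:
        window = 3
    thres = threshold_niblack(img, window_size=window, k=k)
    binary = img > thres
    if not binary.any():
        logger.warning("Niblack produced no positive pixels; image skipped")
        return None
    dt = ndimage.distance_transform_edt(binary)
    pos = np.sort(dt[binary].ravel())
    n_top = max(1, int(math.ceil(top_fraction * pos.size)))
    return float(pos[-n_top:].mean())


def estimate_k2(
    batch: Sequence[VoxelGrid],
    models: Optional[ThresholdModels] = None,
    k2_model: Optional[K2Model] = None,
    k1: float = 2.5,
) -> float:
    """Universal K2 for a batch: mean per-image top-5% DT statistic mapped
    through the K2 model, floored at K1."""
    if not batch:
        raise ValueError("batch must be nonempty")
    k2_model = k2_model or K2Model.from_models(models)
    stats = [s for s in (niblack_top_dt(g) for g in batch) if s is not None]
    if not stats:
        raise ValueError("no image in the batch produced a DT statistic")
    k2 = k2_model(float(np.mean(stats)))
    return max(k2, k1)


def fit_k2_model(
    samples: Sequence[Tuple[VoxelGrid, np.ndarray]],
    k_grid: Sequence[float] = tuple(np.geomspace(1.0, 3000.0, 13)),
    target_deviation: float = -0.2,
    top_fraction: float = 0.05,
    params: Optional[ILEEParams] = None,
) -> K2Model:
    """Refit the K2 estimation model on (image, ground-truth mask) pairs.

    For each sample the single-K segmentation is swept over ``k_grid``; the
    deviation rate — mean over the ground truth's top-5%-DT pixels of
    ``(DT_pred - DT_truth)/DT_truth`` — is interpolated to the K whose value
    is ``target_deviation`` (under-coverage of thick filaments by 20%). The
    optimal log10(K) is then regressed on the Niblack top-5% DT statistic.
    """
    params = params or ILEEParams()
    xs: List[float] = []
    ys: List[float] = []
    for grid, truth in samples:
        truth = np.asarray(truth, dtype=bool)
        dt_truth = ndimage.distance_transform_edt(truth)
        pos = dt_truth[truth]
        cutoff = np.sort(pos)[-max(1, int(math.ceil(top_fraction * pos.size)))]
        top_idx = truth & (dt_truth >= cutoff)
        devs = []
        for k in k_grid:
            res = run_ilee(grid, mode="2d", params=params, ks=(float(k),))
            pred = res.masks["native"].values
            dt_pred = ndimage.distance_transform_edt(pred)
            devs.append(float(np.mean((dt_pred[top_idx] - dt_truth[top_idx]) / dt_truth[top_idx])))
        devs = np.array(devs)
        logk = np.log10(np.asarray(k_grid))
        if devs.min() > target_deviation or devs.max() < target_deviation:
            logger.warning("sample never crosses deviation %.2f; skipped", target_deviation)
            continue
        # deviation grows with K; interpolate log10(K) at the target
        order = np.argsort(devs)
        logk_star = float(np.interp(target_deviation, devs[order], logk[order]))
        stat = niblack_top_dt(grid)
        if stat is None:
            continue
        xs.append(stat)
        ys.append(logk_star)
    if len(xs) < 2:
        raise ValueError("need at least two usable samples to fit the K2 model")
    b, a = np.polyfit(xs, ys, 1)
    if b <= 0:
        logger.warning("fitted K2 model is not increasing (b=%.4f)", b)
    return K2Model(a=float(a), b=float(b), provenance={"n_samples": len(xs)})


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


@dataclass
class ILEEResult:
    """Masks, intermediates, and the full parameter log of one segmentation."""

    mode: str
    masks: Dict[str, BinaryMask]
    per_k_masks: Dict[float, Dict[str, BinaryMask]]
    raw: VoxelGrid  # the mode-input image (z-projection in 2D mode)
    i_pre: VoxelGrid
    g_thres: float
    t_cbg: float
    sigma_cbg: float
    x_peak: float
    edges: EdgeSelection
    ks: Tuple[float, ...]
    params_log: Dict[str, object]


def run_ilee(
    grid: VoxelGrid,
    mode: Literal["2d", "3d"] = "2d",
    params: Optional[ILEEParams] = None,
    models: Optional[ThresholdModels] = None,
    ks: Optional[Sequence[float]] = None,
) -> ILEEResult:
    """Execute the full segmentation: preprocess, NNES/t_cbg, g_thres, edge
    selection, per-K solve/denoise/binarise, and the K1-union-K2 join."""
    params = params or ILEEParams()
    models = models or default_models()
    if mode == "2d" and grid.ndim == 3:
        grid = max_project(grid)
    if mode == "3d" and grid.ndim != 3:
        raise ValueError("3D mode requires a 3D stack")
    i_pre = preprocess(grid, params.preprocess)
    curve = nnes_scan(grid)
    cbg_mode = "2d" if mode == "2d" else params.cbg_model_3d
    t_cbg = coarse_threshold(curve, cbg_mode, models)
    cbg = coarse_background(grid, t_cbg)
    f = grid.geometry.f if mode == "3d" else None
    g_thres = estimate_gradient_threshold(cbg, mode, f=f, models=models)
    G = scharr_magnitude(i_pre)
    edges = select_edges(G, g_thres)

    if ks is None:
        if mode == "3d" and params.use_single_k:
            k_single = params.single_k if params.single_k is not None else params.k1
            ks = (float(k_single),)
        else:
            k2 = params.k2
            if k2 is None:
                k2 = estimate_k2([grid], models=models, k1=params.k1)
                logger.info("estimated K2 = %.2f from the single input image", k2)
            ks = (params.k1, max(float(k2), params.k1))
    ks = tuple(float(k) for k in ks)

    per_k: Dict[float, Dict[str, BinaryMask]] = {}
    if edges.count == 0:
        logger.warning("empty edge selection: returning empty masks")
        empty = binarize(np.full(grid.shape, -1.0), grid.geometry, params)
        union = empty
        for k in ks:
            per_k[k] = empty
    else:
        union = None
        for k in ks:
            i_thres = solve_threshold_surface(i_pre, edges, k, params)
            dif_adj = difference_and_denoise(i_pre, i_thres, params)
            masks = binarize(dif_adj, grid.geometry, params)
            per_k[k] = masks
            if union is None:
                union = {name: BinaryMask(
                    values=m.values.copy(),
                    geometry=m.geometry,
                    provenance=m.provenance,
                    scale=m.scale,
                ) for name, m in masks.items()}
            else:
                for name, m in masks.items():
                    union[name].values |= m.values

    params_log = {
        "mode": mode,
        "k1": params.k1,
        "ks": ks,
        "use_single_k": params.use_single_k,
        "connectivity_2d": params.connectivity_2d,
        "min_element_size": params.min_element_size,
        "oversample_factor": params.oversample_factor,
        "t_cbg": float(t_cbg),
        "g_thres": float(g_thres),
        "sigma_cbg": cbg.sigma_cbg,
        "x_peak": curve.x_peak,
        "models_version": models.version,
    }
    return ILEEResult(
        mode=mode,
        masks=union,
        per_k_masks=per_k,
        raw=grid,
        i_pre=i_pre,
        g_thres=float(g_thres),
        t_cbg=float(t_cbg),
        sigma_cbg=cbg.sigma_cbg,
        x_peak=curve.x_peak,
        edges=edges,
        ks=ks,
        params_log=params_log,
    )
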