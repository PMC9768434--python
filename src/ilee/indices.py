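"""Cytoskeletal indices from segmentation masks.

Twelve indices in five classes:

* density — occupancy, linear density;
* bundling — skewness and CV of the intensity over positive pixels, and the
  distance-transform diameters (TDT: 4x mean DT over all positive pixels;
  SDT: 2x mean DT sampled at skeleton pixels);
* connectivity — total connected elements, segment density;
* branching — total branches, total nodes, static branching activity
  (branches incident to a junction node of degree >= 3 per unit length);
* directionality — local anisotropy of the filament alignment tensor.

Mask provenance follows the pipeline's assignments: in 2D occupancy uses the
native mask while the skeleton-borne indices use the 3x-oversampled mask
(lengths and diameters are rescaled back to native units); in 3D occupancy
uses the native-voxel mask and the rest the cubic-lattice mask.

The skeleton graph (nodes, branches, Euclidean branch lengths) is extracted
in-package from the thinned mask; skeletonisation itself uses Lee's
medial-axis thinning from scikit-image.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _skeletonize

from .core_io import BinaryMask, VoxelGeometry, VoxelGrid

logger = logging.getLogger("ilee")

#: 2D skeleton length kernel: each orthogonal adjacency contributes 1/2 to a
#: pixel, each diagonal adjacency sqrt(2)/2 — summing over pixels counts every
#: step once at its Euclidean length.
LENGTH_KERNEL_2D = np.array(
    [
        [math.sqrt(2) / 2, 0.5, math.sqrt(2) / 2],
        [0.5, 0.0, 0.5],
        [math.sqrt(2) / 2, 0.5, math.sqrt(2) / 2],
    ]
)


# ---------------------------------------------------------------------------
# Skeleton graph
# ---------------------------------------------------------------------------


@dataclass
class Branch:
    path: np.ndarray  # (n_points, ndim) voxel coordinates
    length: float  # Euclidean length in lattice units
    node_start: int
    node_end: int


@dataclass
class SkeletonGraph:
    """Graph view of a 1-element-wide skeleton."""

    skeleton: np.ndarray
    branches: List[Branch]
    node_degrees: Dict[int, int]
    node_is_junction: Dict[int, bool]
    components: int
    total_length: float

    @property
    def n_nodes(self) -> int:
        return len(self.node_degrees)

    @property
    def n_branches(self) -> int:
        return len(self.branches)


def _full_structure(ndim: int) -> np.ndarray:
    return ndimage.generate_binary_structure(ndim, ndim)


def _half_offsets(ndim: int) -> List[Tuple[int, ...]]:
    """One representative per symmetric neighbour pair (full connectivity)."""
    offs = []
    ranges = [(-1, 0, 1)] * ndim
    for off in np.stack(np.meshgrid(*ranges, indexing="ij"), -1).reshape(-1, ndim):
        t = tuple(int(x) for x in off)
        if t == (0,) * ndim:
            continue
        if t > tuple(-x for x in t):
            offs.append(t)
    return offs


def _adjacency(skel: np.ndarray) -> Tuple[np.ndarray, List[List[int]], np.ndarray]:
    """Coordinates, adjacency lists, and degrees of skeleton pixels."""
    coords = np.argwhere(skel)
    n = coords.shape[0]
    ordinal = np.full(skel.shape, -1, dtype=np.int64)
    ordinal[tuple(coords.T)] = np.arange(n)
    adj: List[List[int]] = [[] for _ in range(n)]
    ndim = skel.ndim
    for off in _half_offsets(ndim):
        src = [slice(None)] * ndim
        dst = [slice(None)] * ndim
        ok = True
        for ax, d in enumerate(off):
            if d == 1:
                src[ax] = slice(0, skel.shape[ax] - 1)
                dst[ax] = slice(1, skel.shape[ax])
            elif d == -1:
                if skel.shape[ax] < 2:
                    ok = False
                    break
                src[ax] = slice(1, skel.shape[ax])
                dst[ax] = slice(0, skel.shape[ax] - 1)
        if not ok:
            continue
        a = ordinal[tuple(src)]
        b = ordinal[tuple(dst)]
        both = (a >= 0) & (b >= 0)
        for i, j in zip(a[both].ravel(), b[both].ravel()):
            adj[i].append(int(j))
            adj[j].append(int(i))
    deg = np.array([len(x) for x in adj])
    return coords, adj, deg


def _step_len(c0: np.ndarray, c1: np.ndarray) -> float:
    return float(np.sqrt(((c0 - c1) ** 2).sum()))


def extract_graph(skel: np.ndarray) -> SkeletonGraph:
    """Decompose a skeleton mask into nodes (endpoints and merged junction
    clusters) and branches with Euclidean path lengths."""
    skel = np.asarray(skel, dtype=bool)
    _, n_comp = ndimage.label(skel, structure=_full_structure(skel.ndim))
    coords, adj, deg = _adjacency(skel)
    n = coords.shape[0]
    if n == 0:
        return SkeletonGraph(skel, [], {}, {}, 0, 0.0)

    # node pixels: degree != 2; adjacent junction pixels merge into one node
    is_node_px = deg != 2
    node_id = np.full(n, -1, dtype=np.int64)
    next_id = 0
    junction = deg >= 3
    for i in np.nonzero(is_node_px)[0]:
        if node_id[i] >= 0:
            continue
        node_id[i] = next_id
        if junction[i]:
            stack = [i]
            while stack:
                p = stack.pop()
                for q in adj[p]:
                    if junction[q] and node_id[q] < 0:
                        node_id[q] = next_id
                        stack.append(q)
        next_id += 1
    node_is_junction = {}
    for i in np.nonzero(is_node_px)[0]:
        nid = int(node_id[i])
        node_is_junction[nid] = node_is_junction.get(nid, False) or bool(junction[i])

    branches: List[Branch] = []
    visited = np.zeros(n, dtype=bool)  # deg-2 path pixels consumed
    seen_direct = set()  # node-node pixel adjacencies already emitted

    def emit(path_idx: List[int]) -> None:
        pts = coords[path_idx]
        length = float(np.sqrt(((pts[1:] - pts[:-1]) ** 2).sum(axis=1)).sum())
        branches.append(
            Branch(
                path=pts,
                length=length,
                node_start=int(node_id[path_idx[0]]),
                node_end=int(node_id[path_idx[-1]]),
            )
        )

    for i in np.nonzero(is_node_px)[0]:
        for q in adj[i]:
            if is_node_px[q]:
                if node_id[q] == node_id[i]:
                    continue  # internal edge of a merged junction cluster
                key = (min(int(i), int(q)), max(int(i), int(q)))
                if key in seen_direct:
                    continue
                seen_direct.add(key)
                emit([int(i), int(q)])
            elif not visited[q]:
                path = [int(i), int(q)]
                visited[q] = True
                prev, cur = int(i), int(q)
                while not is_node_px[cur]:
                    nxt = [x for x in adj[cur] if x != prev]
                    if not nxt:
                        break  # dead end inside a path (should not happen)
                    prev, cur = cur, int(nxt[0])
                    if not is_node_px[cur]:
                        if visited[cur]:
                            break
                        visited[cur] = True
                    path.append(cur)
                emit(path)

    # isolated cycles: leftover degree-2 pixels with no node anywhere
    for s in np.nonzero((deg == 2) & ~visited)[0]:
        if visited[s]:
            continue
        path = [int(s)]
        visited[s] = True
        prev, cur = int(s), int(adj[s][0])
        while cur != s:
            visited[cur] = True
            path.append(cur)
            nxt = [x for x in adj[cur] if x != prev]
            if not nxt:
                break
            prev, cur = cur, int(nxt[0])
        path.append(int(s))
        node_id[s] = next_id
        node_is_junction[next_id] = False
        next_id += 1
        emit(path)

    node_degrees: Dict[int, int] = {nid: 0 for nid in range(next_id)}
    for br in branches:
        node_degrees[br.node_start] += 1
        node_degrees[br.node_end] += 1
    total_length = float(sum(br.length for br in branches))
    return SkeletonGraph(skel, branches, node_degrees, node_is_junction, int(n_comp), total_length)


def skeletonize(mask: BinaryMask) -> SkeletonGraph:
    """Lee medial-axis thinning followed by graph extraction."""
    if not mask.values.any():
        return SkeletonGraph(np.zeros(mask.shape, dtype=bool), [], {}, {}, 0, 0.0)
    skel = _skeletonize(mask.values, method="lee").astype(bool)
    return extract_graph(skel)


def kernel_length_2d(skel: np.ndarray) -> float:
    """Total 2D skeleton length by the neighbour kernel (orthogonal step 1,
    diagonal step sqrt(2), each step shared half-and-half by its two pixels)."""
    skel = np.asarray(skel, dtype=np.float64)
    conv = ndimage.convolve(skel, LENGTH_KERNEL_2D, mode="constant", cval=0.0)
    return float(conv[skel > 0].sum())


# ---------------------------------------------------------------------------
# Index report
# ---------------------------------------------------------------------------

INDEX_NAMES = (
    "occupancy",
    "linear_density",
    "skewness",
    "cv",
    "diameter_tdt",
    "diameter_sdt",
    "total_connected_element",
    "segment_density",
    "total_branch",
    "total_node",
    "static_branching_activity",
    "local_anisotropy",
)


@dataclass
class IndexReport:
    occupancy: float = math.nan
    linear_density: float = math.nan  # native px units (length per px^2 or px^3)
    skewness: float = math.nan
    cv: float = math.nan
    diameter_tdt: float = math.nan  # native px
    diameter_sdt: float = math.nan  # native px
    total_connected_element: float = math.nan
    segment_density: float = math.nan  # per native px of length
    total_branch: float = math.nan
    total_node: float = math.nan
    static_branching_activity: float = math.nan  # per native px of length
    local_anisotropy: float = math.nan
    units: Dict[str, str] = field(default_factory=dict)
    physical: Dict[str, float] = field(default_factory=dict)  # µm-based twins
    provenance: Dict[str, str] = field(default_factory=dict)
    flags: List[str] = field(default_factory=list)

    def to_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}


# ---------------------------------------------------------------------------
# Index groups
# ---------------------------------------------------------------------------


def _native_px_scale(native: BinaryMask, work: BinaryMask) -> float:
    """Work-lattice pixels per native pixel along x/y (3 for 3x oversampling)."""
    return native.geometry.u_xy / work.geometry.u_xy


def density_indices(
    native: BinaryMask,
    work: BinaryMask,
    skeleton: SkeletonGraph,
    mode: str,
) -> Tuple[float, float, float]:
    """(occupancy, total length in native px, linear density per native px^n).

    2D lengths come from the neighbour kernel on the (oversampled) skeleton,
    rescaled back to native units; 3D lengths are summed Euclidean graph
    branch lengths on the cubic lattice (whose voxel edge equals the native
    x/y pixel, so they are already in native units).
    """
    occupancy = float(native.values.mean()) if native.values.size else math.nan
    scale = _native_px_scale(native, work)
    if mode == "2d":
        length = kernel_length_2d(skeleton.skeleton) / scale
    else:
        length = skeleton.total_length / scale
    # reference lattice size in native-pixel units, from physical extent
    u_n = native.geometry.u_xy
    phys = float(np.prod(work.shape)) * work.geometry.u_xy**2
    if work.ndim == 3:
        phys *= work.geometry.u_z
        n_ref = phys / u_n**3
    else:
        n_ref = phys / u_n**2
    linear_density = length / n_ref if n_ref else math.nan
    return occupancy, length, linear_density


def bundling_indices(
    raw: VoxelGrid,
    native: BinaryMask,
    dt_mask: BinaryMask,
    skeleton: SkeletonGraph,
) -> Tuple[float, float, float, float]:
    """(skewness, cv, diameter_tdt, diameter_sdt); diameters in dt-mask units.

    Skewness and CV are population moments of the raw intensity over native
    positive pixels; diameters are read off the Euclidean distance transform
    of ``dt_mask`` (the oversampled mask in 2D, cubic in 3D), TDT over all
    positive pixels and SDT at skeleton pixels.
    """
    vals = raw.values[native.values]
    if vals.size < 2:
        return math.nan, math.nan, math.nan, math.nan
    mu = float(vals.mean())
    sigma = float(vals.std())
    skew = float(np.mean(((vals - mu) / sigma) ** 3)) if sigma > 0 else 0.0
    cv = sigma / mu if mu != 0 else math.nan
    if not dt_mask.values.any():
        return skew, cv, math.nan, math.nan
    dt = ndimage.distance_transform_edt(dt_mask.values)
    tdt = 4.0 * float(dt[dt_mask.values].mean())
    sk = skeleton.skeleton
    sdt = 2.0 * float(dt[sk].mean()) if sk.any() else math.nan
    return skew, cv, tdt, sdt


def connectivity_branching_indices(
    skeleton: SkeletonGraph,
    component_mask: Optional[BinaryMask],
    total_length: float,
) -> Tuple[float, float, float, float, float]:
    """(total_connected_element, segment_density, total_branch, total_node,
    static_branching_activity).

    Components are counted on the (oversampled) binary mask in 2D and on the
    skeleton graph in 3D; the normalised indices divide by the total skeleton
    length (native units). A qualifying branch for branching activity has at
    least one endpoint at a junction node (degree >= 3)."""
    if component_mask is not None:
        struct = ndimage.generate_binary_structure(component_mask.ndim, 1)
        _, n_comp = ndimage.label(component_mask.values, structure=struct)
    else:
        n_comp = skeleton.components
    total_branch = float(skeleton.n_branches)
    total_node = float(skeleton.n_nodes)
    qualifying = sum(
        1
        for br in skeleton.branches
        if skeleton.node_degrees.get(br.node_start, 0) >= 3
        or skeleton.node_degrees.get(br.node_end, 0) >= 3
    )
    if total_length > 0:
        seg_density = n_comp / total_length
        sba = qualifying / total_length
    else:
        seg_density = math.nan
        sba = math.nan
    return float(n_comp), seg_density, total_branch, total_node, sba


def _chords(graph: SkeletonGraph, chord_len: int) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decompose branch paths into straight chords: midpoints, unit
    directions, and length weights."""
    mids, dirs, weights = [], [], []
    for br in graph.branches:
        pts = br.path.astype(np.float64)
        i = 0
        while i < len(pts) - 1:
            j = min(i + chord_len, len(pts) - 1)
            v = pts[j] - pts[i]
            norm = float(np.linalg.norm(v))
            if norm > 0:
                mids.append(0.5 * (pts[i] + pts[j]))
                dirs.append(v / norm)
                weights.append(norm)
            i = j
    if not mids:
        return (np.empty((0, graph.skeleton.ndim)),) * 2 + (np.empty(0),)
    return np.array(mids), np.array(dirs), np.array(weights)


def local_anisotropy(
    graph: SkeletonGraph,
    radius: float = 20.0,
    chord_len: int = 5,
    probe_spacing: Optional[float] = None,
) -> Tuple[float, List[Tuple[np.ndarray, float, float]]]:
    """Length-weighted mean over probe regions of the alignment-tensor
    eigenvalue spread lambda_max - lambda_min.

    Each straight chord contributes the rank-2 tensor g g^T weighted by its
    length; probe regions are balls of ``radius`` on a regular grid. Regions
    without chords are excluded. 1 = locally parallel, 0 = isotropic.
    """
    mids, dirs, weights = _chords(graph, chord_len)
    if mids.shape[0] == 0:
        return math.nan, []
    spacing = probe_spacing if probe_spacing is not None else radius
    shape = graph.skeleton.shape
    # at least one probe per axis even when the region is wider than the image
    axes = [np.arange(spacing / 2, s, spacing) if s > spacing / 2 else np.array([s / 2.0]) for s in shape]
    centers = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, len(shape))
    tree = cKDTree(mids)
    probes: List[Tuple[np.ndarray, float, float]] = []
    num = 0.0
    den = 0.0
    for center in centers:
        sel = tree.query_ball_point(center, radius)
        if not sel:
            continue
        g = dirs[sel]
        w = weights[sel]
        T = np.einsum("i,ij,ik->jk", w, g, g) / w.sum()
        eig = np.linalg.eigvalsh(T)
        anis = float(eig[-1] - eig[0])
        region_w = float(w.sum())
        probes.append((center, anis, region_w))
        num += region_w * anis
        den += region_w
    return (num / den if den > 0 else math.nan), probes


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def compute_indices(
    raw: VoxelGrid,
    masks: Dict[str, BinaryMask],
    mode: str,
    anisotropy_radius: float = 20.0,
) -> IndexReport:
    """Compute the full 12-index report from a segmentation's mask set.

    ``raw`` is the mode-input image (the z-projection in 2D mode). ``masks``
    is the dict produced by the pipeline (keys ``native`` and ``oversampled``
    in 2D; ``native``, ``cubic`` and optionally ``oversampled`` in 3D).
    """
    report = IndexReport()
    native = masks["native"]
    if mode == "2d":
        work = masks["oversampled"]
    else:
        work = masks.get("oversampled", masks["cubic"])
    scale = _native_px_scale(native, work)
    report.provenance = {
        "occupancy": "native",
        "skeleton": work.provenance,
        "diameters": work.provenance,
    }
    if not native.values.any():
        report.occupancy = 0.0
        report.flags.append("empty mask: all other indices undefined")
        return report

    graph = skeletonize(work)
    occ, length, lin_density = density_indices(native, work, graph, mode)
    report.occupancy = occ
    report.linear_density = lin_density
    skew, cv, tdt, sdt = bundling_indices(raw, native, work, graph)
    report.skewness = skew
    report.cv = cv
    # diameters back to native px units
    report.diameter_tdt = tdt / scale if not math.isnan(tdt) else tdt
    report.diameter_sdt = sdt / scale if not math.isnan(sdt) else sdt
    comp_mask = work if mode == "2d" else None
    tce, seg, tb, tn, sba = connectivity_branching_indices(graph, comp_mask, length)
    report.total_connected_element = tce
    report.segment_density = seg
    report.total_branch = tb
    report.total_node = tn
    report.static_branching_activity = sba
    anis, _ = local_anisotropy(graph, radius=anisotropy_radius * scale)
    report.local_anisotropy = anis

    u = work.geometry.u_xy  # µm per work-lattice px
    u_native = native.geometry.u_xy
    report.units = {
        "occupancy": "fraction",
        "linear_density": "px/px^n",
        "diameter_tdt": "px",
        "diameter_sdt": "px",
        "segment_density": "1/px",
        "static_branching_activity": "1/px",
    }
    ndim = native.ndim
    report.physical = {
        "linear_density_um": lin_density / u_native ** (ndim - 1) if u_native else math.nan,
        "diameter_tdt_um": tdt * u if not math.isnan(tdt) else math.nan,
        "diameter_sdt_um": sdt * u if not math.isnan(sdt) else math.nan,
    }
    if math.isnan(report.diameter_tdt):
        report.flags.append("diameters undefined")
    return report
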