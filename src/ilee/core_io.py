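"""Image stack I/O, voxel geometry, and dimensional conversions.

This module owns the two carrier types used throughout the pipeline — the
grayscale :class:`VoxelGrid` and the boolean :class:`BinaryMask` — together
with the geometric bookkeeping every downstream stage relies on: z-maximum
projection, resampling of anisotropic confocal voxels to a cubic lattice, and
integer-factor oversampling.

Axis order is fixed as ``(z, y, x)`` for 3D data and ``(y, x)`` for 2D; all
physical lengths are micrometres.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
from skimage.transform import resize

logger = logging.getLogger("ilee")

#: Hard cap on the element count an interpolation is allowed to produce.
DEFAULT_MAX_ELEMENTS = 2**30

Provenance = Literal["native", "cubic", "oversampled"]


def _round_half_away(x: float) -> int:
    """Round half away from zero (used for resampled lattice lengths)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class VoxelGeometry:
    """Physical voxel size: ``u_xy`` per x/y pixel, ``u_z`` per z step (µm).

    ``f = u_xy / u_z`` is the anisotropy factor; it is always derived, never
    stored, and is undefined for 2D grids (``u_z is None``).
    """

    u_xy: float
    u_z: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.u_xy > 0:
            raise ValueError(f"u_xy must be positive, got {self.u_xy}")
        if self.u_z is not None and not self.u_z > 0:
            raise ValueError(f"u_z must be positive, got {self.u_z}")

    @property
    def f(self) -> float:
        if self.u_z is None:
            raise ValueError("anisotropy factor f is undefined for 2D geometry")
        return self.u_xy / self.u_z


@dataclass
class VoxelGrid:
    """A 2D ``(y, x)`` or 3D ``(z, y, x)`` scalar intensity field."""

    values: np.ndarray
    geometry: VoxelGeometry
    bit_depth: int = 12

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D data, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid contains non-finite values")
        if self.values.ndim == 3 and self.geometry.u_z is None:
            raise ValueError("3D grid requires a z voxel size")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape

    @property
    def dynamic_max(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class BinaryMask:
    """Boolean field tagged with provenance and per-axis scale vs. native."""

    values: np.ndarray
    geometry: VoxelGeometry
    provenance: Provenance = "native"
    scale: Tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D mask, got ndim={self.values.ndim}")
        if not self.scale:
            self.scale = (1.0,) * self.values.ndim
        if any(s < 1.0 - 1e-9 for s in self.scale):
            raise ValueError(f"scale factors must be >= 1, got {self.scale}")

    @property
    def ndim(self) -> int:
        return self.values.ndim

    @property
    def shape(self) -> Tuple[int, ...]:
        return self.values.shape


GridOrMask = Union[VoxelGrid, BinaryMask]


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

_OME_SIZE_RE = {
    "x": re.compile(r'PhysicalSizeX="([0-9.eE+-]+)"'),
    "z": re.compile(r'PhysicalSizeZ="([0-9.eE+-]+)"'),
}


def _voxel_size_from_metadata(tif: tifffile.TiffFile) -> Tuple[Optional[float], Optional[float]]:
    """Best-effort (u_xy, u_z) from our own description JSON, OME, or ImageJ."""
    u_xy = u_z = None
    desc = tif.pages[0].description or ""
    try:
        meta = json.loads(desc)
        if isinstance(meta, dict) and "ilee" in meta:
            return meta.get("u_xy"), meta.get("u_z")
    except (json.JSONDecodeError, TypeError):
        pass
    if tif.ome_metadata:
        mx = _OME_SIZE_RE["x"].search(tif.ome_metadata)
        mz = _OME_SIZE_RE["z"].search(tif.ome_metadata)
        u_xy = float(mx.group(1)) if mx else None
        u_z = float(mz.group(1)) if mz else None
        return u_xy, u_z
    if tif.imagej_metadata:
        u_z = tif.imagej_metadata.get("spacing")
        tags = tif.pages[0].tags
        if "XResolution" in tags:
            num, den = tags["XResolution"].value
            if num:
                u_xy = den / num
    return u_xy, u_z


def read_stack(
    path: Union[str, Path],
    u_xy: Optional[float] = None,
    u_z: Optional[float] = None,
    bit_depth: Optional[int] = None,
) -> VoxelGrid:
    """Read a single-channel grayscale TIFF / OME-TIFF into a :class:`VoxelGrid`.

    Multi-page files become 3D grids in ``(z, y, x)`` order. Voxel sizes are
    taken from the explicit arguments first, then from file metadata; a 3D
    stack with no z spacing from either source is rejected. ``bit_depth``
    defaults to metadata, else the storage dtype width.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        for bad in ("C", "S"):
            if bad in axes:
                raise ValueError(
                    f"{path.name}: multi-channel/RGB input not supported "
                    f"(offending axis {bad!r} in axes {axes!r}); convert to "
                    "single-channel grayscale first"
                )
        data = series.asarray()
        meta_xy, meta_z = _voxel_size_from_metadata(tif)
        meta_depth = None
        desc = tif.pages[0].description or ""
        try:
            meta = json.loads(desc)
            if isinstance(meta, dict):
                meta_depth = meta.get("bit_depth")
        except (json.JSONDecodeError, TypeError):
            pass
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise ValueError(f"{path.name}: expected 2D or 3D grayscale data, got shape {data.shape}")
    u_xy = u_xy if u_xy is not None else meta_xy
    u_z = u_z if u_z is not None else meta_z
    if u_xy is None:
        raise ValueError(f"{path.name}: no x/y voxel size in metadata and no override given")
    if data.ndim == 3 and u_z is None:
        raise ValueError(f"{path.name}: 3D stack without z voxel size; pass u_z explicitly")
    if bit_depth is None:
        bit_depth = meta_depth if meta_depth is not None else data.dtype.itemsize * 8
    geometry = VoxelGeometry(u_xy=u_xy, u_z=u_z if data.ndim == 3 else None)
    return VoxelGrid(values=data.astype(np.float64), geometry=geometry, bit_depth=int(bit_depth))


def write_stack(grid: VoxelGrid, path: Union[str, Path]) -> None:
    """Write a grid as an integer grayscale TIFF with a JSON geometry sidecar tag."""
    path = Path(path)
    dtype = np.uint8 if grid.bit_depth <= 8 else np.uint16
    data = np.clip(np.rint(grid.values), 0, grid.dynamic_max).astype(dtype)
    desc = json.dumps(
        {
            "ilee": True,
            "u_xy": grid.geometry.u_xy,
            "u_z": grid.geometry.u_z,
            "bit_depth": grid.bit_depth,
        }
    )
    tifffile.imwrite(path, data, description=desc)


def write_mask(mask: BinaryMask, path: Union[str, Path]) -> None:
    """Export a binary mask as 8-bit TIFF (0/255)."""
    tifffile.imwrite(Path(path), (mask.values.astype(np.uint8) * 255))


# ---------------------------------------------------------------------------
# Dimensional conversions
# ---------------------------------------------------------------------------


def max_project(grid: VoxelGrid) -> VoxelGrid:
    """z-axis maximum projection of a 3D stack to a 2D image."""
    if grid.ndim != 3:
        raise ValueError("max_project requires a 3D grid")
    proj = grid.values.max(axis=0)
    return VoxelGrid(
        values=proj,
        geometry=VoxelGeometry(u_xy=grid.geometry.u_xy),
        bit_depth=grid.bit_depth,
    )


def _resize_float(values: np.ndarray, shape: Sequence[int], order: int) -> np.ndarray:
    return resize(
        values.astype(np.float64),
        tuple(shape),
        order=order,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def to_cubic(obj: GridOrMask, order: int = 3) -> GridOrMask:
    """Resample the z axis by 1/f so physical spacing is equal on all axes.

    Intensity grids are spline-interpolated at the given ``order``; masks are
    interpolated as {0.0, 1.0} floats and re-binarized at 0.5. The new z
    length is rounded half-away-from-zero (logged).
    """
    if obj.ndim != 3:
        raise ValueError("to_cubic requires 3D input")
    f = obj.geometry.f
    nz, ny, nx = obj.shape
    nz_new = max(1, _round_half_away(nz / f))
    if nz_new != nz / f:
        logger.debug("to_cubic: z length %s/%s=%.3f rounded to %d", nz, f, nz / f, nz_new)
    new_geom = VoxelGeometry(u_xy=obj.geometry.u_xy, u_z=obj.geometry.u_z * nz / nz_new)
    if isinstance(obj, VoxelGrid):
        out = _resize_float(obj.values, (nz_new, ny, nx), order)
        return VoxelGrid(values=out, geometry=new_geom, bit_depth=obj.bit_depth)
    out = _resize_float(obj.values, (nz_new, ny, nx), order) >= 0.5
    scale = (obj.scale[0] * nz_new / nz,) + tuple(obj.scale[1:])
    return BinaryMask(values=out, geometry=new_geom, provenance="cubic", scale=scale)


def oversample(
    obj: GridOrMask,
    factors: Sequence[float],
    order: int = 3,
    max_elements: int = DEFAULT_MAX_ELEMENTS,
) -> GridOrMask:
    """Cubic-spline (bicubic in 2D) upsampling by per-axis factors.

    Masks are interpolated via their float representation and re-binarized at
    0.5. Note that the segmentation pipeline does *not* oversample masks: it
    interpolates the float difference image and thresholds at 0 afterwards
    (see :mod:`ilee.ilee_core`).
    """
    factors = tuple(float(s) for s in factors)
    if len(factors) != obj.ndim:
        raise ValueError(f"need {obj.ndim} factors, got {len(factors)}")
    if any(s < 1 for s in factors):
        raise ValueError(f"oversampling factors must be >= 1, got {factors}")
    new_shape = tuple(_round_half_away(n * s) for n, s in zip(obj.shape, factors))
    n_elem = int(np.prod([float(n) for n in new_shape]))
    if n_elem > max_elements:
        raise MemoryError(
            f"refusing to interpolate to {n_elem} elements (cap {max_elements})"
        )
    geom = obj.geometry
    if obj.ndim == 3:
        new_geom = VoxelGeometry(
            u_xy=geom.u_xy * obj.shape[1] / new_shape[1],
            u_z=geom.u_z * obj.shape[0] / new_shape[0],
        )
    else:
        new_geom = VoxelGeometry(u_xy=geom.u_xy * obj.shape[-1] / new_shape[-1])
    if isinstance(obj, VoxelGrid):
        out = _resize_float(obj.values, new_shape, order)
        return VoxelGrid(values=out, geometry=new_geom, bit_depth=obj.bit_depth)
    out = _resize_float(obj.values, new_shape, order) >= 0.5
    scale = tuple(s0 * n1 / n0 for s0, n0, n1 in zip(obj.scale, obj.shape, new_shape))
    return BinaryMask(values=out, geometry=new_geom, provenance="oversampled", scale=scale)
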