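"""EM intensity normalization: anisotropy-aware pseudo-3D CLAHE and median denoising.

The pseudo-3D CLAHE runs three independent 2D CLAHE passes over orthogonal
plane stacks — front (XY), top (XZ), side (YZ) — and combines them voxel-wise.
Window sizes are specified physically (nm) and converted per axis, so
anisotropic voxels yield rectangular sliding windows: a 260.4 nm tile at
(10, 3.255, 3.255) nm spacing is an 80x80 px window in XY but 26x80 px in
XZ/YZ.  This corrects the bias an isotropic pixel window would introduce on
milling-direction planes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import exposure

from .grid import VoxelGrid, as_uint8

__all__ = ["clahe_anisotropic", "clahe_window_px", "median_denoise"]

_COMBINE = {"mean": lambda s: np.mean(s, axis=0),
            "min": lambda s: np.min(s, axis=0),
            "max": lambda s: np.max(s, axis=0)}


def clahe_window_px(tile_nm: float, spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    """Per-axis window size in px for a physical tile: round(tile_nm / spacing)."""
    return tuple(int(round(tile_nm / s)) for s in spacing)


def _window_px(tile_nm: float, spacing_nm: float, n: int) -> int:
    """Physical tile size expressed in pixels along one axis, clipped to the image."""
    return int(min(max(round(tile_nm / spacing_nm), 1), n))


def _clahe_planes(vol: np.ndarray, kernel: tuple[int, int], clip: float, nbins: int) -> np.ndarray:
    """2D CLAHE applied to every plane of ``vol`` along axis 0; returns float in [0,1]."""
    out = np.empty(vol.shape, dtype=np.float64)
    for i in range(vol.shape[0]):
        plane = vol[i]
        if plane.max() == plane.min():  # no contrast to equalize
            out[i] = plane / 255.0
            continue
        out[i] = exposure.equalize_adapthist(
            plane, kernel_size=kernel, clip_limit=clip, nbins=nbins
        )
    return out


def clahe_anisotropic(
    grid: VoxelGrid,
    tile_nm: float = 416.0,
    clip_limit: float = 3.0,
    combine: str = "mean",
    nbins: int = 256,
) -> VoxelGrid:
    """Pseudo-3D CLAHE: three orthogonal 2D passes with physically sized windows.

    Parameters
    ----------
    grid : VoxelGrid
        8-bit intensity volume.
    tile_nm : float
        Sliding-window size in nm; per-axis window (px) = round(tile_nm / spacing).
        Default 416 nm (~128 px in-plane at 3.255 nm/px).
    clip_limit : float
        Classical CLAHE clip factor: histogram bins are clipped at
        ``clip_limit`` times the mean bin count (converted internally to
        skimage's normalized limit as clip_limit/nbins).
    combine : {"mean", "min", "max"}
        Voxel-wise combination of the XY, XZ and YZ passes (default mean).

    Returns
    -------
    VoxelGrid
        8-bit, same shape and spacing.
    """
    if not grid.is_8bit:
        raise ValueError("clahe_anisotropic requires an 8-bit grid")
    if combine not in _COMBINE:
        raise ValueError(f"combine must be one of {sorted(_COMBINE)}")
    nz, ny, nx = grid.shape
    c, b, a = grid.spacing
    wz, wy, wx = (_window_px(tile_nm, s, n) for s, n in zip((c, b, a), (nz, ny, nx)))
    if wy < 2 or wx < 2:
        raise ValueError(f"tile_nm={tile_nm} gives a <2 px window in-plane "
                         f"(spacing {grid.spacing})")
    wz = max(wz, 2)  # a 1-px axial window would degenerate the orthogonal passes
    skclip = min(clip_limit / nbins, 1.0)
    vol = grid.values

    passes = np.empty((3,) + grid.shape, dtype=np.float64)
    # front (XY): planes along z, window (y, x)
    passes[0] = _clahe_planes(vol, (wy, wx), skclip, nbins)
    # top (XZ): planes along y, window (z, x)
    passes[1] = np.moveaxis(
        _clahe_planes(np.moveaxis(vol, 1, 0), (wz, wx), skclip, nbins), 0, 1
    )
    # side (YZ): planes along x, window (z, y)
    passes[2] = np.moveaxis(
        _clahe_planes(np.moveaxis(vol, 2, 0), (wz, wy), skclip, nbins), 0, 2
    )
    combined = _COMBINE[combine](passes)
    return grid.with_values(as_uint8(combined), name=f"{grid.name}+clahe")


def median_denoise(grid: VoxelGrid, radius_nm: float) -> VoxelGrid:
    """Median filter with per-axis half-widths round(radius_nm / spacing).

    Suppresses detector shot noise.  ``radius_nm`` must be at least the largest
    in-plane spacing and must give a window of >=3 voxels on at least one axis.
    """
    if radius_nm < max(grid.spacing[1:]):
        raise ValueError(f"radius_nm={radius_nm} is below the in-plane spacing "
                         f"{max(grid.spacing[1:])}")
    half = tuple(int(round(radius_nm / s)) for s in grid.spacing)
    size = tuple(2 * h + 1 for h in half)
    if max(size) < 3:
        raise ValueError(f"radius_nm={radius_nm} covers <3 voxels on every axis")
    out = ndimage.median_filter(grid.values, size=size, mode="nearest")
    return grid.with_values(out, name=f"{grid.name}+median")
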