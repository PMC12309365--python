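"""Read and write volumetric stacks (multi-page TIFF and HDF5).

Spacing is stored as ImageJ-style metadata in TIFF and as dataset attributes
in HDF5; an explicit ``spacing`` argument always overrides file metadata.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import tifffile
import h5py

from .grid import VoxelGrid, ProbabilityMap, LabelVolume, LabelEntry

__all__ = ["read_stack", "write_stack", "read_labels", "write_labels"]

_TIFF_EXT = (".tif", ".tiff")
_HDF5_EXT = (".h5", ".hdf5", ".hdf")


def _tiff_spacing(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    meta = tf.imagej_metadata or {}
    page = tf.pages[0]
    try:
        xres = page.tags["XResolution"].value
        yres = page.tags["YResolution"].value
        a = xres[1] / xres[0]
        b = yres[1] / yres[0]
    except (KeyError, ZeroDivisionError):
        return None
    c = meta.get("spacing")
    if c is None:
        return None
    return (float(c), float(b), float(a))


def read_stack(path: str | os.PathLike, spacing=None, name: str | None = None) -> VoxelGrid:
    """Load a TIFF or HDF5 volume as a :class:`VoxelGrid`.

    Parameters
    ----------
    path : str
        Multi-page TIFF (``.tif``/``.tiff``) or HDF5 (``.h5``/``.hdf5``) file.
    spacing : (c, b, a), optional
        Voxel size in nm per (z, y, x) axis; overrides any file metadata.
        Required when the file carries none.

    Returns
    -------
    VoxelGrid
        Slice order preserved (first page / first axis = z), bit depth preserved.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    origin = (0.0, 0.0, 0.0)
    if ext in _TIFF_EXT:
        with tifffile.TiffFile(path) as tf:
            values = tf.asarray()
            meta_spacing = _tiff_spacing(tf)
    elif ext in _HDF5_EXT:
        with h5py.File(path, "r") as f:
            if "values" not in f:
                raise ValueError(f"{path}: no 'values' dataset")
            ds = f["values"]
            values = ds[()]
            meta_spacing = tuple(ds.attrs["spacing"]) if "spacing" in ds.attrs else None
            if "origin" in ds.attrs:
                origin = tuple(float(o) for o in ds.attrs["origin"])
    else:
        raise ValueError(f"unsupported extension {ext!r} (use .tif/.tiff/.h5/.hdf5)")

    if values.ndim == 2:
        values = values[np.newaxis]
    if values.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {values.shape}")
    spacing = spacing if spacing is not None else meta_spacing
    if spacing is None:
        raise ValueError(f"{path}: no spacing metadata; pass spacing=(c,b,a) in nm")
    return VoxelGrid(values, spacing=spacing, origin=origin,
                     name=name if name is not None else os.path.basename(path))


def write_stack(grid: VoxelGrid, path: str | os.PathLike) -> None:
    """Write a grid to TIFF or HDF5 (format from extension); round-trip is bit-exact."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _TIFF_EXT:
        c, b, a = grid.spacing
        values = grid.values
        if values.dtype == np.float64:
            values = values.astype(np.float32)  # TIFF convention for probability maps
        tifffile.imwrite(
            path,
            values,
            imagej=True,
            resolution=(1.0 / a, 1.0 / b),
            metadata={"spacing": c, "unit": "nm", "axes": "ZYX"},
        )
    elif ext in _HDF5_EXT:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("values", data=grid.values)
            ds.attrs["spacing"] = grid.spacing
            ds.attrs["origin"] = grid.origin
            ds.attrs["name"] = grid.name
    else:
        raise ValueError(f"unsupported extension {ext!r} (use .tif/.tiff/.h5/.hdf5)")


def write_labels(labels: LabelVolume, path: str | os.PathLike) -> None:
    """Write a label volume (HDF5 only: integer ids plus a JSON label table)."""
    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("labels", data=labels.labels)
        ds.attrs["spacing"] = labels.spacing
        ds.attrs["origin"] = labels.origin
        table = {
            str(lid): [e.class_name, e.instance_index, bool(e.clipped_by_boundary)]
            for lid, e in labels.table.items()
        }
        ds.attrs["table"] = json.dumps(table)


def read_labels(path: str | os.PathLike) -> LabelVolume:
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        ds = f["labels"]
        raw = json.loads(ds.attrs["table"])
        table = {
            int(lid): LabelEntry(cls, int(idx), bool(clip))
            for lid, (cls, idx, clip) in raw.items()
        }
        return LabelVolume(ds[()], table=table, spacing=tuple(ds.attrs["spacing"]),
                           origin=tuple(ds.attrs["origin"]))
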