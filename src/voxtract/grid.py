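"""Volumetric grid containers with physical (nm) voxel spacing.

Axis convention: arrays are indexed ``(z, y, x)`` and spacing is given as
``(c, b, a)`` nm per axis in the same order.  FIB-SEM stacks are typically
anisotropic (the milling step ``c`` exceeds the in-plane pixel size ``a = b``),
so every nm<->voxel conversion goes through these containers rather than
assuming cubic voxels.  Voxel coordinates are 0-based and a voxel's physical
position is its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["VoxelGrid", "ProbabilityMap", "LabelVolume", "LabelEntry", "as_uint8"]


def _validate_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError(f"spacing must have 3 entries (c, b, a), got {spacing}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"all spacings must be positive, got {spacing}")
    return spacing


def as_uint8(values: np.ndarray) -> np.ndarray:
    """Convert an array to 8-bit with round-half-up; floats in [0,1] are scaled."""
    if values.dtype == np.uint8:
        return values
    arr = np.asarray(values, dtype=np.float64)
    if arr.size and arr.max() <= 1.0 and np.issubdtype(values.dtype, np.floating):
        arr = arr * 255.0
    arr = np.clip(np.floor(arr + 0.5), 0, 255)
    return arr.astype(np.uint8)


@dataclass
class VoxelGrid:
    """Scalar 3D image with anisotropic physical spacing.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        8-bit intensities (0-255) or unit-interval floats, indexed (z, y, x).
    spacing : (c, b, a)
        Physical size of one voxel along (z, y, x), in nm.  All positive.
    origin : (z, y, x)
        nm offset of voxel (0, 0, 0)'s center.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:  # single slice
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D (z,y,x), got ndim={self.values.ndim}")
        self.spacing = _validate_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.dtype == np.uint8:
            pass
        elif np.issubdtype(self.values.dtype, np.integer):
            if self.values.size and (self.values.min() < 0 or self.values.max() > 255):
                raise ValueError("integer grids must contain only values in [0, 255]")
            self.values = self.values.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def is_8bit(self) -> bool:
        return self.values.dtype == np.uint8

    def voxel_volume_nm3(self) -> float:
        c, b, a = self.spacing
        return c * b * a

    def physical_coords(self, indices: np.ndarray) -> np.ndarray:
        """Physical nm coordinates (z,y,x) of voxel indices (k,j,i): origin + index*spacing."""
        idx = np.atleast_2d(np.asarray(indices, dtype=np.float64))
        return idx * np.array(self.spacing) + np.array(self.origin)

    def nm_to_voxels(self, length_nm: float) -> tuple[float, ...]:
        """A physical length expressed in voxels along each axis (z, y, x)."""
        return tuple(length_nm / s for s in self.spacing)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "VoxelGrid":
        return replace(self, values=values, name=self.name if name is None else name)

    def to_uint8(self) -> "VoxelGrid":
        return self.with_values(as_uint8(self.values))


@dataclass
class ProbabilityMap(VoxelGrid):
    """Per-voxel class probability in [0, 1] on the same grid convention."""

    class_name: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        super().__post_init__()
        if self.values.size and (self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9):
            raise ValueError(
                f"probabilities must lie in [0,1]; got range "
                f"[{self.values.min():.4g}, {self.values.max():.4g}]"
            )
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass(frozen=True)
class LabelEntry:
    class_name: str
    instance_index: int
    clipped_by_boundary: bool = False


@dataclass
class LabelVolume:
    """Integer instance labels (0 = unassigned) with a label table."""

    labels: np.ndarray
    table: Mapping[int, LabelEntry]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D (z,y,x)")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _validate_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        self.table = dict(self.table)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"labels present without table entry: {sorted(missing)}")
        # instance indices must be unique within a class
        seen: dict[tuple[str, int], int] = {}
        for lid, entry in self.table.items():
            key = (entry.class_name, entry.instance_index)
            if key in seen:
                raise ValueError(
                    f"duplicate instance index {key} for labels {seen[key]} and {lid}"
                )
            seen[key] = lid

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, label_id: int) -> np.ndarray:
        """Binary mask of one label id."""
        if label_id not in self.table:
            raise KeyError(f"unknown label id {label_id}")
        return self.labels == label_id

    def class_mask(self, class_name: str) -> np.ndarray:
        ids = [lid for lid, e in self.table.items() if e.class_name == class_name]
        return np.isin(self.labels, ids)


def check_same_grid(*grids) -> None:
    """Raise if shapes or spacings differ between grids/label volumes."""
    ref = grids[0]
    for g in grids[1:]:
        if g.shape != ref.shape:
            raise ValueError(f"shape mismatch: {g.shape} vs {ref.shape}")
        if tuple(g.spacing) != tuple(ref.spacing):
            raise ValueError(f"spacing mismatch: {g.spacing} vs {ref.spacing}")
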