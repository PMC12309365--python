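"""Triangulated surface reconstruction and surface-level measurements.

Surfaces are extracted by marching cubes at a scalar isovalue.  On binary
(0/255) input the vertices can only sit at exact mid-points between voxel
centers, which both terraces the surface and imposes a floor on the smallest
nonzero distance measurable between two objects; on scalar input (e.g. AIVE
output) vertices interpolate to arbitrary fractional positions, removing that
floor.  The default isovalue of 64 is the center of the product dynamic range
of a probability (0-1) times an 8-bit intensity: 50% x 50% = 25% of 255.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.spatial import ConvexHull
from skimage import measure

from .grid import VoxelGrid

__all__ = [
    "SurfaceMesh",
    "MeshMeasures",
    "marching_cubes",
    "mesh_measures",
    "min_measurable_distance",
    "feret_diameter",
    "marching_cubes_case_classes",
]

_DEGENERATE_TOL = 1e-6  # nm


@dataclass
class SurfaceMesh:
    """Triangulated surface in physical nm coordinates (z, y, x).

    ``vertex_area`` assigns each vertex one third of the summed areas of its
    incident triangles, so vertex areas total the full mesh area and per-vertex
    quantities can be area-weighted.
    """

    vertices: np.ndarray          # (n, 3) nm
    faces: np.ndarray             # (m, 3) vertex indices
    vertex_area: np.ndarray = field(default=None)  # (n,) nm^2
    watertight: bool = False
    label: int | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertex_area is None:
            self.vertex_area = _vertex_areas(self.vertices, self.faces)

    @property
    def is_empty(self) -> bool:
        return len(self.faces) == 0

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def triangles(self) -> np.ndarray:
        """(m, 3, 3) array of triangle vertex coordinates."""
        return self.vertices[self.faces]

    def export(self, path: str) -> None:
        """Export as PLY or STL (from extension)."""
        self.as_trimesh().export(path)

    @classmethod
    def load(cls, path: str, label: int | None = None) -> "SurfaceMesh":
        tm = trimesh.load(path, force="mesh", process=False)
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces),
                   watertight=bool(tm.is_watertight), label=label)


def _vertex_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    areas = np.zeros(len(vertices))
    if len(faces) == 0:
        return areas
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    tri_area = 0.5 * np.linalg.norm(cross, axis=1)
    for k in range(3):
        np.add.at(areas, faces[:, k], tri_area / 3.0)
    return areas


def _clean(vertices: np.ndarray, faces: np.ndarray):
    """Merge duplicate vertices and drop degenerate triangles."""
    tm = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=6)
    tri = tm.triangles
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    ok = 0.5 * np.linalg.norm(cross, axis=1) > _DEGENERATE_TOL**2
    tm.update_faces(ok)
    tm.remove_unreferenced_vertices()
    return tm


def marching_cubes(grid: VoxelGrid, isovalue: float = 64.0, label: int | None = None) -> SurfaceMesh:
    """Extract the isosurface of a scalar grid at ``isovalue``.

    Vertices are linearly interpolated between voxel centers along grid edges
    at the isovalue crossing, then scaled into nm by the grid spacing (binary
    input therefore places vertices at exact voxel-center mid-points).  A grid
    entirely above or below the isovalue yields an empty mesh.
    """
    values = grid.values.astype(np.float64)
    if min(grid.shape) < 2:
        raise ValueError("marching cubes needs >=2 voxels per axis")
    if values.max() <= isovalue or values.min() >= isovalue:
        return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64),
                           watertight=False, label=label)
    verts, faces, _, _ = measure.marching_cubes(values, level=isovalue,
                                                spacing=grid.spacing)
    verts = verts + np.asarray(grid.origin)
    tm = _clean(verts, faces)
    if tm.is_watertight:
        # orient faces consistently with normals outward, so signed
        # distances follow the negative-inside convention
        tm.fix_normals()
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces),
                       watertight=bool(tm.is_watertight), label=label)


@dataclass
class MeshMeasures:
    """Surface area, enclosed volume, sphericity 36*pi*V^2/A^3, Euler characteristic."""

    area_nm2: float
    volume_nm3: float
    sphericity: float
    euler_characteristic: int
    closed: bool

    @property
    def volume_valid(self) -> bool:
        return self.closed


def mesh_measures(mesh: SurfaceMesh) -> MeshMeasures:
    """Area, volume, sphericity and Euler characteristic of a surface.

    Volume uses the signed tetrahedron sum, valid only for closed meshes;
    on an open mesh volume and sphericity are returned NaN (flagged via
    ``closed=False``) while the area remains valid.
    """
    if mesh.is_empty:
        return MeshMeasures(0.0, 0.0, float("nan"), 0, closed=False)
    tm = mesh.as_trimesh()
    area = float(tm.area)
    closed = bool(tm.is_watertight)
    if closed:
        volume = float(abs(tm.volume))
        sphericity = 36.0 * np.pi * volume**2 / area**3 if area > 0 else float("nan")
    else:
        volume = float("nan")
        sphericity = float("nan")
    return MeshMeasures(area, volume, sphericity, int(tm.euler_number), closed)


def min_measurable_distance(spacing) -> float:
    """Smallest nonzero surface separation measurable on binarized input.

    With binary data, marching-cubes vertices sit at mid-points between voxel
    centers, so the closest two distinct surfaces can approach is set by half
    the voxel pitch.  The largest spacing never hosts the minimum (separations
    along it are strictly larger), leaving the Pythagorean combination of the
    two smallest half-spacings: sqrt((a/2)^2 + (b/2)^2).  For (10, 3.255,
    3.255) nm voxels this is 2.3 nm.
    """
    s = sorted(float(x) for x in spacing)
    if len(s) != 3 or s[0] <= 0:
        raise ValueError("spacing must be three positive values")
    a, b = s[0], s[1]
    return float(np.hypot(a / 2.0, b / 2.0))


def feret_diameter(mask: np.ndarray, spacing=(1.0, 1.0)) -> float:
    """Maximum caliper (Feret) diameter of a 2D binary region, in nm.

    Each foreground pixel contributes its four corners so a region s pixels
    wide spans exactly s pixel units; the maximum pairwise distance is taken
    over the convex hull of those corners.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ValueError("feret_diameter expects a 2D mask")
    if not mask.any():
        raise ValueError("empty mask")
    sy, sx = (float(s) for s in spacing)
    jj, ii = np.nonzero(mask)
    corners = np.concatenate([
        np.stack([(jj + dy) * sy, (ii + dx) * sx], axis=1)
        for dy in (-0.5, 0.5) for dx in (-0.5, 0.5)
    ])
    if len(np.unique(corners, axis=0)) < 3:
        pts = corners
    else:
        pts = corners[ConvexHull(corners).vertices]
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def _cube_rotations():
    """The 24 rotation matrices of the cube as corner permutations."""
    corners = np.array(list(itertools.product([0, 1], repeat=3)))  # (8,3) z,y,x
    mats = []
    for perm in itertools.permutations(range(3)):
        for signs in itertools.product([1, -1], repeat=3):
            m = np.zeros((3, 3))
            for r, (p, s) in enumerate(zip(perm, signs)):
                m[r, p] = s
            if np.linalg.det(m) > 0:
                mats.append(m)
    perms = []
    centered = corners - 0.5
    for m in mats:
        mapped = centered @ m.T + 0.5
        perm = [int(np.where((corners == mc).all(axis=1))[0][0]) for mc in mapped]
        perms.append(tuple(perm))
    return sorted(set(perms))


def marching_cubes_case_classes(complement: bool = True, reflections: bool = False) -> int:
    """Count equivalence classes of the 256 cube corner-sign configurations.

    Marching cubes triangulates each cube from the above/below-isovalue signs
    of its 8 corners (2^8 = 256 configurations); symmetry reduces these to a
    small canonical set.  ``complement=True`` additionally identifies a
    configuration with its inverted-signs counterpart, ``reflections=True``
    extends rotations to the full (improper) symmetry group.  Returned for
    documentation of the topology pool available to binary data.
    """
    corners = np.array(list(itertools.product([0, 1], repeat=3)))
    perms = _cube_rotations()
    if reflections:
        mirrored = []
        mirror = corners.copy()
        mirror[:, 0] = 1 - mirror[:, 0]
        mperm = [int(np.where((corners == mc).all(axis=1))[0][0]) for mc in mirror]
        for p in perms:
            mirrored.append(tuple(p[m] for m in mperm))
        perms = sorted(set(perms) | set(mirrored))

    seen = set()
    classes = 0
    for config in range(256):
        if config in seen:
            continue
        classes += 1
        bits = [(config >> k) & 1 for k in range(8)]
        orbit = set()
        for p in perms:
            variants = [tuple(bits[p[k]] for k in range(8))]
            if complement:
                variants.append(tuple(1 - v for v in variants[0]))
            for v in variants:
                orbit.add(sum(b << k for k, b in enumerate(v)))
        seen |= orbit
    return classes
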