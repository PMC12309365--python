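"""Synthetic phantom volumes emulating FIB-SEM inputs.

Generates membranous phantoms (shells, balls, tubes, dumbbells, intruded
sphere pairs) on an anisotropic voxel grid, renders 8-bit EM-like intensity
with membrane contrast brighter than matrix (heavy-metal staining polarity)
plus Gaussian and shot noise, and simulates the outputs of multiple AI
segmentation models that agree in object interiors but disagree at
boundaries.  Everything is deterministic for a fixed seed so the full
pipeline is testable without any acquired data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import VoxelGrid, ProbabilityMap, LabelVolume, LabelEntry

__all__ = [
    "Ball", "Shell", "Tube", "dumbbell", "PhantomSpec",
    "make_phantom", "intruded_spheres", "simulate_ai_variants",
]

# default grid emulates the acquisition regime: 3.255 nm in-plane, 10 nm milling
DEFAULT_SPACING = (10.0, 3.255, 3.255)


def _coords_nm(shape, spacing, origin=(0.0, 0.0, 0.0)):
    axes = [np.arange(n) * s + o for n, s, o in zip(shape, spacing, origin)]
    return np.meshgrid(*axes, indexing="ij")


@dataclass(frozen=True)
class Ball:
    """Solid sphere: membrane band at the surface, matter-filled interior."""

    center_nm: tuple[float, float, float]
    radius_nm: float
    filled: bool = True

    def sdf(self, zz, yy, xx):
        cz, cy, cx = self.center_nm
        return np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2) - self.radius_nm


@dataclass(frozen=True)
class Shell(Ball):
    """Hollow membranous sphere (alias of Ball; interior filling optional)."""


@dataclass(frozen=True)
class Tube:
    """Capsule between two points; ``filled=False`` gives a membrane-only tube."""

    p1_nm: tuple[float, float, float]
    p2_nm: tuple[float, float, float]
    radius_nm: float
    filled: bool = True

    def sdf(self, zz, yy, xx):
        p1 = np.asarray(self.p1_nm)
        d = np.asarray(self.p2_nm) - p1
        L2 = float(d @ d)
        vz, vy, vx = zz - p1[0], yy - p1[1], xx - p1[2]
        if L2 == 0:
            t = 0.0
        else:
            t = np.clip((vz * d[0] + vy * d[1] + vx * d[2]) / L2, 0.0, 1.0)
        qz, qy, qx = vz - t * d[0], vy - t * d[1], vx - t * d[2]
        return np.sqrt(qz**2 + qy**2 + qx**2) - self.radius_nm


def dumbbell(center_nm, lobe_radius_nm, lobe_separation_nm, tunnel_radius_nm,
             axis=2):
    """Two matter-filled lobes joined by a membrane-only (matrix-free) tube.

    The canonical nanotunnel phantom: the organelle solid stays one connected
    component while its matrix splits into two.
    """
    c = np.asarray(center_nm, dtype=float)
    offset = np.zeros(3)
    offset[axis] = lobe_separation_nm / 2.0
    a, b = c - offset, c + offset
    return [
        Ball(tuple(a), lobe_radius_nm),
        Ball(tuple(b), lobe_radius_nm),
        Tube(tuple(a), tuple(b), tunnel_radius_nm, filled=False),
    ]


@dataclass
class PhantomSpec:
    """Recipe for one phantom volume.

    Intensities follow stained-membrane contrast polarity (membrane brightest);
    noise is additive Gaussian plus salt-and-pepper shot corruption.
    """

    shape: tuple[int, int, int] = (40, 96, 96)
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    objects: list = field(default_factory=list)
    membrane_thickness_nm: float = 30.0
    membrane_intensity: int = 200
    matter_intensity: int = 140
    cytosol_intensity: int = 90
    noise_sd: float = 10.0
    shot_fraction: float = 0.02
    seed: int = 0

    def extent_nm(self):
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


def make_phantom(spec: PhantomSpec):
    """Render a phantom: EM intensity grid, truth maps, and instance labels.

    Returns
    -------
    (em, truth_membrane, truth_matter, labels)
        ``em`` is the noisy 8-bit intensity volume; the truth maps are the
        noise-free membership functions (1.0 on the membrane band / filled
        interior); ``labels`` indexes each object's solid as one instance.
    """
    zz, yy, xx = _coords_nm(spec.shape, spec.spacing)
    half_t = spec.membrane_thickness_nm / 2.0
    extent = spec.extent_nm()

    membrane = np.zeros(spec.shape, dtype=bool)
    matter = np.zeros(spec.shape, dtype=bool)
    labels = np.zeros(spec.shape, dtype=np.int32)
    table: dict[int, LabelEntry] = {}

    sdfs = []
    for i, obj in enumerate(spec.objects):
        sdf = obj.sdf(zz, yy, xx)
        if (sdf > 0).all() and not (np.abs(sdf) <= half_t).any():
            raise ValueError(f"object {i} lies outside the grid extent {extent}")
        sdfs.append(sdf)

    for i, (obj, sdf) in enumerate(zip(spec.objects, sdfs)):
        band = np.abs(sdf) <= half_t
        # a membrane is continuous with, not threaded through, a lumen it
        # meets: suppress the band strictly inside another object's interior
        for j, (other, osdf) in enumerate(zip(spec.objects, sdfs)):
            if j != i and getattr(other, "filled", True):
                band &= ~(osdf < -half_t)
        membrane |= band
        if getattr(obj, "filled", True):
            matter |= sdf < -half_t
        lid = i + 1
        solid = sdf <= half_t
        labels[solid] = lid
        table[lid] = LabelEntry(class_name=type(obj).__name__.lower(),
                                instance_index=lid)
    matter &= ~membrane

    intensity = np.full(spec.shape, float(spec.cytosol_intensity))
    intensity[matter] = spec.matter_intensity
    intensity[membrane] = spec.membrane_intensity

    rng = np.random.default_rng(spec.seed)
    noisy = intensity + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    if spec.shot_fraction > 0:
        shot = rng.random(spec.shape) < spec.shot_fraction
        noisy[shot] = rng.choice([0.0, 255.0], size=int(shot.sum()))
    em_values = np.clip(np.floor(noisy + 0.5), 0, 255).astype(np.uint8)

    em = VoxelGrid(em_values, spacing=spec.spacing, name="phantom-em")
    t_memb = ProbabilityMap(membrane.astype(np.float64), spacing=spec.spacing,
                            class_name="Memb")
    t_matter = ProbabilityMap(matter.astype(np.float64), spacing=spec.spacing,
                              class_name="Matter")
    lab = LabelVolume(labels, table=table, spacing=spec.spacing)
    return em, t_memb, t_matter, lab


def intruded_spheres(
    diameter_vox: int = 128,
    intrusion_depth_nm: float = 100.0,
    mode: str = "intruded",
    seam_nm: float = 0.0,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    pad_vox: int = 4,
):
    """Two labeled sphere solids, externally tangent or with one intruding.

    In ``intruded`` mode sphere #2 extends ``intrusion_depth_nm`` into a
    matching invagination of sphere #1 (seam gap ``seam_nm``, 0 by default);
    in ``tangent`` mode the spheres touch externally.  At zero depth the two
    modes coincide.  Returns (solid1, solid2, spacing); spacing defaults to
    1 nm/voxel so distances read in voxel units.
    """
    if mode not in ("intruded", "tangent"):
        raise ValueError("mode must be 'intruded' or 'tangent'")
    if spacing[0] != spacing[1] or spacing[1] != spacing[2]:
        raise ValueError("intruded_spheres assumes isotropic spacing")
    s = spacing[0]
    R = diameter_vox * s / 2.0
    depth = 0.0 if mode == "tangent" else float(intrusion_depth_nm)
    if depth >= 2 * R:
        raise ValueError("intrusion depth must be smaller than the sphere diameter")
    gap = 2 * R - depth  # center separation along x

    nz = ny = diameter_vox + 2 * pad_vox
    nx = int(np.ceil((2 * R + gap) / s)) + 2 * pad_vox
    shape = (nz, ny, nx)
    zz, yy, xx = _coords_nm(shape, spacing)
    c1 = (nz * s / 2.0, ny * s / 2.0, pad_vox * s + R)
    c2 = (c1[0], c1[1], c1[2] + gap)

    d1 = np.sqrt((zz - c1[0]) ** 2 + (yy - c1[1]) ** 2 + (xx - c1[2]) ** 2)
    d2 = np.sqrt((zz - c2[0]) ** 2 + (yy - c2[1]) ** 2 + (xx - c2[2]) ** 2)
    solid2 = d2 <= R
    solid1 = (d1 <= R) & (d2 > R + seam_nm)
    return solid1, solid2, spacing


def simulate_ai_variants(
    truth: ProbabilityMap,
    k: int = 6,
    boundary_jitter_nm: float = 10.0,
    interior_conf: float = 0.9,
    correlation_nm: float = 30.0,
    boundary_noise_sd: float = 0.5,
    noise_correlation_nm: float = 10.0,
    seed: int = 0,
) -> list[ProbabilityMap]:
    """Simulate k AI model outputs that agree in interiors, disagree at boundaries.

    Each variant perturbs the truth in two boundary-localized ways that mimic
    how independently trained models disagree: (1) the boundary transition is
    displaced by a smooth zero-mean Gaussian random field with pointwise
    standard deviation ``boundary_jitter_nm`` and correlation length
    ``correlation_nm`` (systematic per-model boundary shift); (2) patchy
    probability speckle (standard deviation ``boundary_noise_sd``, correlation
    length ``noise_correlation_nm``) is added within two jitter lengths of the
    true boundary, emulating the model-specific spurious blobs and dropouts
    that appear where a classifier is uncertain.
    Interior probabilities stay at ``interior_conf``, so variants differ only
    near boundaries.  Deterministic for a fixed seed; zero jitter returns the
    truth scaled by ``interior_conf`` for every variant.
    """
    if k < 2:
        raise ValueError("need k >= 2 variants")
    mask = truth.values > 0.5
    spacing = truth.spacing
    if boundary_jitter_nm == 0:
        base = interior_conf * mask.astype(np.float64)
        return [replace(truth, values=base.copy(), class_name=f"{truth.class_name}~v{i}")
                for i in range(k)]

    sdf = (ndimage.distance_transform_edt(~mask, sampling=spacing)
           - ndimage.distance_transform_edt(mask, sampling=spacing))
    noise_band = np.abs(sdf) <= 2.0 * boundary_jitter_nm
    sigmas = tuple(correlation_nm / s for s in spacing)
    variants = []
    for i in range(k):
        rng = np.random.default_rng([seed, i])
        field_ = ndimage.gaussian_filter(rng.standard_normal(truth.shape), sigma=sigmas)
        sd = field_.std()
        if sd > 0:
            field_ *= boundary_jitter_nm / sd
        jittered = sdf < field_
        values = interior_conf * jittered.astype(np.float64)
        if boundary_noise_sd > 0:
            speckle = ndimage.gaussian_filter(
                rng.standard_normal(truth.shape),
                sigma=tuple(noise_correlation_nm / s for s in spacing))
            ssd = speckle.std()
            if ssd > 0:
                speckle *= boundary_noise_sd / ssd
            values = np.clip(values + speckle * noise_band, 0.0, 1.0)
        variants.append(replace(truth, values=values,
                                class_name=f"{truth.class_name}~v{i}"))
    return variants
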