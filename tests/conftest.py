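import numpy as np
import pytest

from voxtract.grid import VoxelGrid


def scalar_ball(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                center=(48.0, 48.0, 48.0), radius=30.0, slope=64.0):
    """Anti-aliased ball: 128 at the surface, graded over ~2 voxels."""
    zz, yy, xx = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij")
    dist = np.sqrt((zz - center[0]) ** 2 + (yy - center[1]) ** 2
                   + (xx - center[2]) ** 2)
    vals = np.clip(128.0 + (radius - dist) * slope, 0, 255).astype(np.uint8)
    return VoxelGrid(vals, spacing=spacing), dist


def binary_ball(shape=(48, 48, 48), spacing=(2.0, 2.0, 2.0),
                center=(48.0, 48.0, 48.0), radius=30.0):
    _, dist = scalar_ball(shape, spacing, center, radius)
    return VoxelGrid((dist <= radius).astype(np.uint8) * 255, spacing=spacing)


@pytest.fixture(scope="session")
def ball_grid():
    grid, _ = scalar_ball()
    return grid


@pytest.fixture(scope="session")
def ball_radius():
    return 30.0
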