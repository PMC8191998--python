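"""Dual-channel cuboid extraction and stochastic training augmentation.

The classifier sees a fixed physical window of 50 x 50 x 100 um around each
candidate, resampled to 50 x 50 x 20 voxels, from both channels.  At the
reference 2 x 2 x 5 um voxel size this is a 25 x 25 x 20 voxel crop upsampled
x2 in-plane with z untouched.

Training-time augmentation applies, each with 10% likelihood and independently
of the others: a flip along one axis, a rotation about one axis (uniform in
[-45 deg, 45 deg]), and a circular translation along one axis (up to 5% of the
axis length).  Both channels always receive the identical transform so that
dual-channel structure stays co-located.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from somafind.volume_io import PlaneStackVolume, VoxelGeometry, validate_channel_pair

__all__ = [
    "CUBOID_SHAPE",
    "CUBOID_PHYSICAL_UM",
    "Cuboid",
    "extract_cuboid",
    "augment",
    "standardize",
]

CUBOID_SHAPE = (50, 50, 20)  # (x, y, z) voxels fed to the network
CUBOID_PHYSICAL_UM = (50.0, 50.0, 100.0)  # physical window per axis


@dataclass
class Cuboid:
    """A (50, 50, 20, 2) patch: axes (x, y, z, channel), channel 0 = signal."""

    data: np.ndarray
    source_position: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        expected = CUBOID_SHAPE + (2,)
        if self.data.shape != expected:
            raise ValueError(f"cuboid shape must be {expected}, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cuboid contains non-finite values")


def _crop_padded(data: np.ndarray, start: np.ndarray, size: np.ndarray) -> np.ndarray:
    """Crop ``data[z, y, x]`` with constant-0 padding outside the volume."""
    out = np.zeros(tuple(size), dtype=np.float64)
    lo_src = np.maximum(start, 0)
    hi_src = np.minimum(start + size, data.shape)
    if np.any(hi_src <= lo_src):
        return out
    lo_dst = lo_src - start
    hi_dst = lo_dst + (hi_src - lo_src)
    out[lo_dst[0] : hi_dst[0], lo_dst[1] : hi_dst[1], lo_dst[2] : hi_dst[2]] = data[
        lo_src[0] : hi_src[0], lo_src[1] : hi_src[1], lo_src[2] : hi_src[2]
    ]
    return out


def extract_cuboid(
    signal: PlaneStackVolume,
    autofluo: PlaneStackVolume,
    position: tuple[float, float, float],
    geometry: VoxelGeometry | None = None,
) -> Cuboid:
    """Extract the dual-channel cuboid centred on ``position`` (x, y, z voxels).

    The physical window extent per axis is rounded to the nearest whole voxel
    count before resampling (linear interpolation) to the network shape.
    Regions outside the volume are zero-padded, so edge candidates keep the
    exact output shape.
    """
    validate_channel_pair(signal, autofluo)
    if geometry is None:
        geometry = signal.geometry
    spacing_xyz = np.array([geometry.dx, geometry.dy, geometry.dz])
    window_xyz = np.maximum(
        np.rint(np.array(CUBOID_PHYSICAL_UM) / spacing_xyz).astype(int), 1
    )
    pos_xyz = np.rint(np.asarray(position, dtype=float)).astype(int)
    start_xyz = pos_xyz - window_xyz // 2

    window_zyx = window_xyz[::-1]
    start_zyx = start_xyz[::-1]
    target_zyx = (CUBOID_SHAPE[2], CUBOID_SHAPE[1], CUBOID_SHAPE[0])
    channels = []
    for vol in (signal, autofluo):
        crop = _crop_padded(np.asarray(vol.data, dtype=np.float64), start_zyx, window_zyx)
        if tuple(crop.shape) != target_zyx:
            crop = resize(
                crop, target_zyx, order=1, mode="constant", cval=0.0,
                anti_aliasing=False, preserve_range=True,
            )
        channels.append(crop.transpose(2, 1, 0))  # -> (x, y, z)
    return Cuboid(np.stack(channels, axis=-1), tuple(float(v) for v in position))


_ROTATION_PLANES = {0: (1, 2), 1: (0, 2), 2: (0, 1)}  # plane orthogonal to each axis


def augment(cuboid: Cuboid, rng: np.random.Generator) -> Cuboid:
    """Stochastically augment a cuboid (both channels identically).

    Each family fires independently with probability 0.10; within a family the
    axis (and angle or shift) is drawn uniformly.  Order: flip, rotation,
    circular translation.  Reproducible given the generator state.
    """
    data = cuboid.data
    # (i) flip along one axis
    if rng.random() < 0.10:
        axis = int(rng.integers(3))
        data = np.flip(data, axis=axis)
    # (ii) rotation about one axis, in [-45, 45] degrees
    if rng.random() < 0.10:
        axis = int(rng.integers(3))
        angle = rng.uniform(-45.0, 45.0)
        data = ndimage.rotate(
            data,
            angle,
            axes=_ROTATION_PLANES[axis],
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
    # (iii) circular translation along one axis, up to 5% of its length
    if rng.random() < 0.10:
        axis = int(rng.integers(3))
        max_shift = max(1, int(0.05 * data.shape[axis]))
        shift = int(rng.integers(-max_shift, max_shift + 1))
        data = np.roll(data, shift, axis=axis)
    return Cuboid(np.ascontiguousarray(data), cuboid.source_position)


def standardize(data: np.ndarray, sd_floor: float = 1e-6) -> np.ndarray:
    """Per-channel standardisation (zero mean, unit SD over the cuboid).

    Makes the classifier invariant to acquisition gain/offset without needing
    dataset-wide statistics; the SD floor guards degenerate constant patches.
    """
    data = np.asarray(data, dtype=np.float32)
    mean = data.mean(axis=(0, 1, 2), keepdims=True)
    sd = data.std(axis=(0, 1, 2), keepdims=True)
    return (data - mean) / np.maximum(sd, sd_floor)
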