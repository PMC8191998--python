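"""High-sensitivity classical detection of cell candidates.

The detector is deliberately biased towards over-detection: every object of
roughly soma-like brightness and size becomes a candidate, and the downstream
classifier is responsible for rejecting artefacts.  The pipeline is

1. per-plane median filtering followed by a (negated) Laplacian-of-Gaussian,
   which enhances bright blobs at the soma scale;
2. per-plane thresholding at ``mean + k * SD`` of the filtered plane;
3. a 3D ellipsoidal overlap filter that keeps positions where at least a
   given fraction of an ellipsoidal footprint covers thresholded voxels
   (removes neurites and speckle);
4. merging of 3D-connected surviving voxels into candidate clusters;
5. iterative ellipsoidal splitting of clusters too large to be one soma;
6. centroid extraction (3D mean coordinate of the cluster's voxels).

All sizes are specified in micrometres and converted to voxels through the
volume's :class:`~somafind.volume_io.VoxelGeometry`, so the same parameters
work across anisotropic acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy import ndimage

from somafind.volume_io import PlaneStackVolume, VoxelGeometry

__all__ = [
    "DetectionParameters",
    "CandidateCluster",
    "filter_plane",
    "threshold_plane",
    "ellipsoid_footprint",
    "overlap_filter",
    "merge_structures",
    "is_too_large",
    "split_cluster",
    "detect_candidates",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity for merging
_CONN6 = ndimage.generate_binary_structure(3, 1)  # face-adjacent erosion element


@dataclass(frozen=True)
class DetectionParameters:
    """Tunable candidate-detection parameters (defaults are the reference set).

    Attributes
    ----------
    soma_diameter:
        Expected in-plane soma diameter in um.  The single most
        data-dependent parameter; retune for differently sized cell types.
    gaussian_sigma:
        Laplacian-of-Gaussian sigma as a fraction of ``soma_diameter``.
    threshold_multiplier:
        Per-plane binarisation threshold: mean + this many SDs of the
        filtered plane.
    ellipsoid_lateral_width / ellipsoid_axial_width:
        Full widths (diameters) in um of the ellipsoidal overlap footprint.
        Raise the axial width when plane spacing is coarse (e.g. 30 um at
        40 um plane spacing) so somata still span the footprint axially.
    overlap_fraction:
        Fraction of the footprint that must cover thresholded voxels.
    median_window:
        In-plane median-filter window edge (voxels, odd).  ``None`` derives
        it from the smoothing scale: ``max(3, round(gaussian_sigma *
        soma_diameter / dx))`` forced odd.
    split_iterations:
        Maximum erosion iterations when splitting over-large clusters.
    too_large_slack:
        A cluster is split when its voxel count exceeds this factor times
        the voxel volume of a soma-diameter sphere (slack absorbs the
        partial-volume fringe of a digitised ball).
    """

    soma_diameter: float = 16.0
    gaussian_sigma: float = 0.2
    threshold_multiplier: float = 10.0
    ellipsoid_lateral_width: float = 6.0
    ellipsoid_axial_width: float = 15.0
    overlap_fraction: float = 0.6
    median_window: int | None = None
    split_iterations: int = 10
    too_large_slack: float = 1.5

    def __post_init__(self) -> None:
        positives = (
            self.soma_diameter,
            self.gaussian_sigma,
            self.threshold_multiplier,
            self.ellipsoid_lateral_width,
            self.ellipsoid_axial_width,
            self.overlap_fraction,
            self.split_iterations,
            self.too_large_slack,
        )
        if not all(v > 0 for v in positives):
            raise ValueError("all detection parameters must be positive")
        if self.overlap_fraction > 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.median_window is not None and self.median_window < 1:
            raise ValueError("median_window must be >= 1")

    def with_axial_width(self, width_um: float) -> "DetectionParameters":
        return replace(self, ellipsoid_axial_width=width_um)

    def median_window_voxels(self, geometry: VoxelGeometry) -> int:
        if self.median_window is not None:
            w = self.median_window
        else:
            w = max(3, round(self.gaussian_sigma * self.soma_diameter / geometry.dx))
        return w if w % 2 == 1 else w + 1


@dataclass
class CandidateCluster:
    """A connected set of surviving voxels forming one cell candidate.

    ``voxels`` is an (M, 3) integer array of (x, y, z) voxel coordinates; the
    centroid is their arithmetic mean.
    """

    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=np.int64))
        if self.voxels.size == 0 or self.voxels.shape[1] != 3:
            raise ValueError("cluster needs a non-empty (M, 3) voxel array")

    @property
    def centroid(self) -> np.ndarray:
        """Fractional (x, y, z) mean coordinate of the constituent voxels."""
        return self.voxels.mean(axis=0)

    @property
    def n_voxels(self) -> int:
        return self.voxels.shape[0]


def filter_plane(
    plane: np.ndarray, params: DetectionParameters, geometry: VoxelGeometry
) -> np.ndarray:
    """Median filter then negated Laplacian of Gaussian (bright blobs -> peaks)."""
    plane = np.asarray(plane, dtype=np.float64)
    if plane.size == 0:
        raise ValueError("empty plane")
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    w = params.median_window_voxels(geometry)
    smoothed = ndimage.median_filter(plane, size=w)
    sigma_um = params.gaussian_sigma * params.soma_diameter
    sigma = (sigma_um / geometry.dy, sigma_um / geometry.dx)  # plane is [y, x]
    return -ndimage.gaussian_laplace(smoothed, sigma=sigma)


def threshold_plane(filtered: np.ndarray, multiplier: float) -> np.ndarray:
    """Binarise one plane at ``mean + multiplier * SD`` (population SD, strict >).

    A constant plane has zero SD and yields an all-false mask.
    """
    filtered = np.asarray(filtered, dtype=np.float64)
    if filtered.size < 2:
        raise ValueError("plane must have at least 2 voxels")
    return filtered > filtered.mean() + multiplier * filtered.std()


def ellipsoid_footprint(
    lateral_width: float, axial_width: float, geometry: VoxelGeometry
) -> np.ndarray:
    """Integer voxel offsets (i, j, k) inside an anisotropy-aware ellipsoid.

    Widths are full axis lengths in um; an offset is included when
    ``(i*dx/a)^2 + (j*dy/a)^2 + (k*dz/c)^2 <= 1`` with semi-axes
    ``a = lateral_width / 2`` and ``c = axial_width / 2``.  The set is
    symmetric under negation of any axis and always contains the origin.
    """
    if lateral_width / geometry.dx < 1 or lateral_width / geometry.dy < 1:
        raise ValueError("lateral width smaller than one voxel")
    if axial_width / geometry.dz < 1:
        raise ValueError("axial width smaller than one voxel")
    a = lateral_width / 2.0
    c = axial_width / 2.0
    ri = int(math.floor(a / geometry.dx))
    rj = int(math.floor(a / geometry.dy))
    rk = int(math.floor(c / geometry.dz))
    offsets = [
        (i, j, k)
        for i, j, k in product(range(-ri, ri + 1), range(-rj, rj + 1), range(-rk, rk + 1))
        if (i * geometry.dx / a) ** 2 + (j * geometry.dy / a) ** 2 + (k * geometry.dz / c) ** 2
        <= 1.0 + 1e-12
    ]
    return np.array(offsets, dtype=np.int64)


def _footprint_kernel(offsets: np.ndarray) -> np.ndarray:
    """Dense odd-shaped [z, y, x] kernel for a symmetric offset set."""
    ri = int(np.max(np.abs(offsets[:, 0])))
    rj = int(np.max(np.abs(offsets[:, 1])))
    rk = int(np.max(np.abs(offsets[:, 2])))
    kernel = np.zeros((2 * rk + 1, 2 * rj + 1, 2 * ri + 1), dtype=np.int32)
    kernel[offsets[:, 2] + rk, offsets[:, 1] + rj, offsets[:, 0] + ri] = 1
    return kernel


def overlap_filter(
    mask: np.ndarray, footprint: np.ndarray, overlap_fraction: float
) -> np.ndarray:
    """Keep positions where >= ``overlap_fraction`` of the footprint is true.

    ``mask`` is a [z, y, x] boolean volume; ``footprint`` an (K, 3) offset
    array from :func:`ellipsoid_footprint`.  Footprint positions that extend
    past the volume treat out-of-bounds voxels as false, so the criterion
    naturally tightens at borders (where surface artefacts concentrate).
    """
    footprint = np.atleast_2d(np.asarray(footprint))
    if footprint.size == 0:
        raise ValueError("empty footprint")
    kernel = _footprint_kernel(footprint)
    counts = ndimage.correlate(
        np.asarray(mask, dtype=np.int32), kernel, mode="constant", cval=0
    )
    needed = overlap_fraction * footprint.shape[0]
    return counts >= needed - 1e-9


def merge_structures(surviving: np.ndarray) -> list[CandidateCluster]:
    """Group surviving voxels into clusters by 3D 26-connectivity."""
    labels, n = ndimage.label(np.asarray(surviving, dtype=bool), structure=_CONN26)
    clusters = []
    for component in range(1, n + 1):
        zz, yy, xx = np.nonzero(labels == component)
        clusters.append(CandidateCluster(np.column_stack([xx, yy, zz])))
    return clusters


def reference_soma_voxels(params: DetectionParameters, geometry: VoxelGeometry) -> float:
    """Voxel volume of a sphere of diameter ``soma_diameter``."""
    r = params.soma_diameter / 2.0
    return (4.0 / 3.0) * math.pi * r**3 / geometry.voxel_volume


def is_too_large(
    cluster: CandidateCluster, params: DetectionParameters, geometry: VoxelGeometry
) -> bool:
    """True when the cluster is too big to be one soma and should be split."""
    return cluster.n_voxels > params.too_large_slack * reference_soma_voxels(params, geometry)


def _dedupe_positions(
    positions: list[np.ndarray], radius_um: float, geometry: VoxelGeometry
) -> list[np.ndarray]:
    """Greedy merge of candidate positions closer than ``radius_um``.

    The iterative filter revisits the same soma on successive erosions;
    positions within half a soma diameter are averaged into one.
    """
    scale = np.array([geometry.dx, geometry.dy, geometry.dz])
    merged: list[list[np.ndarray]] = []
    for pos in positions:
        for group in merged:
            rep = np.mean(group, axis=0)
            if np.linalg.norm((pos - rep) * scale) < radius_um:
                group.append(pos)
                break
        else:
            merged.append([pos])
    return [np.mean(group, axis=0) for group in merged]


def split_cluster(
    cluster: CandidateCluster,
    params: DetectionParameters,
    geometry: VoxelGeometry,
) -> list[CandidateCluster]:
    """Split an over-large cluster into individual candidates.

    The ellipsoidal overlap criterion is applied to the cluster's own voxels;
    connected passing positions are recorded as candidate coordinates, the
    cluster mask is eroded (face-adjacent element), and the process repeats
    for up to ``split_iterations`` rounds or until nothing passes.  Recorded
    positions closer than half a soma diameter are merged, and each original
    voxel is assigned to its nearest surviving position.  If no position ever
    passes, the cluster is returned unsplit.
    """
    offsets = ellipsoid_footprint(
        params.ellipsoid_lateral_width, params.ellipsoid_axial_width, geometry
    )
    vox = cluster.voxels
    lo = vox.min(axis=0)
    hi = vox.max(axis=0)
    pad = np.max(np.abs(offsets), axis=0) + 1
    origin = lo - pad  # (x, y, z) of local array origin
    shape_xyz = hi - lo + 2 * pad + 1
    local = np.zeros((shape_xyz[2], shape_xyz[1], shape_xyz[0]), dtype=bool)
    rel = vox - origin
    local[rel[:, 2], rel[:, 1], rel[:, 0]] = True

    positions: list[np.ndarray] = []
    mask = local
    for _ in range(params.split_iterations):
        if not mask.any():
            break
        passing = overlap_filter(mask, offsets, params.overlap_fraction) & mask
        if not passing.any():
            break
        labels, n = ndimage.label(passing, structure=_CONN26)
        centroids = ndimage.center_of_mass(passing, labels, range(1, n + 1))
        for cz, cy, cx in centroids:
            positions.append(np.array([cx, cy, cz]) + origin)
        mask = ndimage.binary_erosion(mask, structure=_CONN6)

    if not positions:
        return [cluster]
    centers = _dedupe_positions(positions, params.soma_diameter / 2.0, geometry)
    if len(centers) == 1:
        return [cluster]
    scale = np.array([geometry.dx, geometry.dy, geometry.dz])
    dists = np.stack(
        [np.linalg.norm((vox - c) * scale, axis=1) for c in centers], axis=1
    )
    assignment = np.argmin(dists, axis=1)
    return [
        CandidateCluster(vox[assignment == i])
        for i in range(len(centers))
        if np.any(assignment == i)
    ]


def detect_candidates(
    signal: PlaneStackVolume, params: DetectionParameters | None = None
) -> list[CandidateCluster]:
    """Run the full candidate-detection pipeline on the signal channel.

    Deterministic: identical inputs always give identical candidate lists.
    """
    if params is None:
        params = DetectionParameters()
    geometry = signal.geometry
    mask = np.empty(signal.shape, dtype=bool)
    for k in range(signal.n_planes):
        filtered = filter_plane(signal.plane(k), params, geometry)
        mask[k] = threshold_plane(filtered, params.threshold_multiplier)

    offsets = ellipsoid_footprint(
        params.ellipsoid_lateral_width, params.ellipsoid_axial_width, geometry
    )
    surviving = overlap_filter(mask, offsets, params.overlap_fraction)
    clusters = merge_structures(surviving)

    out: list[CandidateCluster] = []
    for cluster in clusters:
        if is_too_large(cluster, params, geometry):
            out.extend(split_cluster(cluster, params, geometry))
        else:
            out.append(cluster)
    return out
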