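"""Seeded dual-channel phantom volumes with known ground truth.

The generator emulates the features of dual-channel whole-brain fluorescence
data that the detection pipeline relies on:

* bright, roughly spherical cell somata (~16 um diameter) present ONLY in the
  signal channel (a cytoplasmic label has no counterpart in the
  autofluorescence channel);
* bright non-cellular artefacts present in BOTH channels — surface debris
  hugging a volume face, vessel-like bright cylinders, and cell-sized blobs;
* a flat background with independent Gaussian noise per channel;
* anisotropic axial sampling (reference voxel size 2 x 2 x 5 um).

Every output is a pure function of the spec (including its seed), so tests
and the acceptance pipeline need no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from somafind.cuboid_extraction import Cuboid, extract_cuboid
from somafind.volume_io import (
    CellRecord,
    Channel,
    PlaneStackVolume,
    VoxelGeometry,
)

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "CellTruth",
    "ArtefactTruth",
    "generate_phantom",
    "downsample_axially",
    "make_labelled_cuboid_set",
    "LABEL_CELL",
    "LABEL_ARTEFACT",
]

LABEL_CELL = 1
LABEL_ARTEFACT = 0

ArtefactKind = Literal["surface_debris", "vessel_segment", "bright_blob"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one dual-channel phantom.

    Intensity units are arbitrary: the detector thresholds on per-plane
    statistics, so only the signal-to-noise ratio matters.  The defaults put
    the peak cell amplitude at ~20 noise SDs above background so that the
    default detection parameters (mean + 10 SD threshold) fire reliably.

    ``placement`` is ``"separated"`` (all object centres at least one mean
    soma diameter apart — the clean regime) or ``"clustered"`` (cells placed
    in touching groups, to exercise cluster splitting).
    """

    shape: tuple[int, int, int] = (128, 128, 32)  # (x, y, z) voxels
    geometry: VoxelGeometry = VoxelGeometry(2.0, 2.0, 5.0)
    n_cells: int = 25
    cell_diameter_mean: float = 16.0  # um
    cell_diameter_sd: float = 1.0  # um
    cell_intensity: float = 200.0
    n_artefacts: int = 0
    artefact_kinds: tuple[ArtefactKind, ...] = ("bright_blob", "vessel_segment", "surface_debris")
    artefact_intensity: float = 200.0
    background_level: float = 100.0
    noise_sd: float = 10.0
    edge_width: float = 2.0  # um, soft edge of vessel/debris artefacts
    placement: Literal["separated", "clustered"] = "separated"
    cluster_size: int = 2  # cells per fused group in clustered mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0 or self.n_artefacts < 0:
            raise ValueError("object counts must be >= 0")
        if len(self.shape) != 3 or any(s < 4 for s in self.shape):
            raise ValueError("shape must be three extents of at least 4 voxels")


@dataclass(frozen=True)
class CellTruth:
    center: tuple[float, float, float]  # (x, y, z) voxels
    diameter: float  # um


@dataclass(frozen=True)
class ArtefactTruth:
    center: tuple[float, float, float]
    kind: str


@dataclass
class GroundTruth:
    """True object positions for a generated phantom."""

    cells: list[CellTruth] = field(default_factory=list)
    artefacts: list[ArtefactTruth] = field(default_factory=list)

    def cell_records(self) -> list[CellRecord]:
        return [CellRecord(*c.center, label="cell") for c in self.cells]

    def artefact_records(self) -> list[CellRecord]:
        return [CellRecord(*a.center, label="artefact") for a in self.artefacts]


def _render_ball(
    data: np.ndarray,
    center: np.ndarray,
    diameter_um: float,
    intensity: float,
    geometry: VoxelGeometry,
    edge_um: float,
) -> None:
    """Add a physically spherical dome-profile blob to ``data[z, y, x]``.

    The intensity falls off as a Gaussian dome of scale ``diameter / 4``
    (peak at the centre, ~13% of peak at radius ``diameter / 2``), mimicking
    the PSF-blurred appearance of a cytoplasmically filled soma: brightest
    mid-cell, with the stated diameter as the visible extent.
    """
    radius = diameter_um / 2.0
    spacing = np.array([geometry.dz, geometry.dy, geometry.dx])
    czyx = center[::-1]
    extent_um = radius + 3 * edge_um
    lo = np.maximum(np.floor(czyx - extent_um / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(czyx + extent_um / spacing).astype(int) + 1, data.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[(np.arange(lo[a], hi[a]) - czyx[a]) * spacing[a] for a in range(3)],
        indexing="ij",
    )
    dist_sq = sum(g**2 for g in grids)
    scale = radius / 2.0
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += intensity * np.exp(
        -dist_sq / (2.0 * scale**2)
    )


def _render_cylinder(
    data: np.ndarray,
    center: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    radius_um: float,
    intensity: float,
    geometry: VoxelGeometry,
    edge_um: float,
) -> None:
    """Add a soft-edged bright cylinder (vessel-like segment)."""
    spacing = np.array([geometry.dz, geometry.dy, geometry.dx])
    d_zyx = direction[::-1] / np.linalg.norm(direction)
    czyx = center[::-1]
    half = length_um / 2.0
    extent_um = half + radius_um + 3 * edge_um
    lo = np.maximum(np.floor(czyx - extent_um / spacing).astype(int), 0)
    hi = np.minimum(np.ceil(czyx + extent_um / spacing).astype(int) + 1, data.shape)
    if np.any(hi <= lo):
        return
    grids = np.meshgrid(
        *[(np.arange(lo[a], hi[a]) - czyx[a]) * spacing[a] for a in range(3)],
        indexing="ij",
    )
    along = sum(g * d for g, d in zip(grids, d_zyx))
    along_clamped = np.clip(along, -half, half)
    radial_sq = sum(
        (g - along_clamped * d) ** 2 for g, d in zip(grids, d_zyx)
    )
    outside = np.maximum(np.sqrt(radial_sq) - radius_um, 0.0) + np.maximum(
        np.abs(along) - half, 0.0
    )
    data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += intensity * np.exp(
        -(outside**2) / (2.0 * edge_um**2)
    )


def _min_pairwise_um(
    candidate: np.ndarray, placed: list[np.ndarray], geometry: VoxelGeometry
) -> float:
    if not placed:
        return math.inf
    scale = np.array([geometry.dx, geometry.dy, geometry.dz])
    return min(np.linalg.norm((candidate - p) * scale) for p in placed)


def _draw_center(
    rng: np.random.Generator, shape: Sequence[int], margin_vox: np.ndarray
) -> np.ndarray:
    return np.array(
        [rng.uniform(margin_vox[a], shape[a] - 1 - margin_vox[a]) for a in range(3)]
    )


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[PlaneStackVolume, PlaneStackVolume, GroundTruth]:
    """Generate (signal, autofluorescence, truth) for a phantom spec.

    Cells are rendered only into the signal channel; artefacts into both.
    Raises ``RuntimeError`` when separated placement cannot be satisfied
    after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.geometry
    nx, ny, nz = spec.shape
    zyx_shape = (nz, ny, nx)

    signal = rng.normal(spec.background_level, spec.noise_sd, zyx_shape)
    autofluo = rng.normal(spec.background_level, spec.noise_sd, zyx_shape)

    truth = GroundTruth()
    placed: list[np.ndarray] = []
    spacing = np.array([g.dx, g.dy, g.dz])
    min_sep = spec.cell_diameter_mean  # um, separated-mode contract

    def place_separated(margin_um: float) -> np.ndarray:
        margin_vox = margin_um / spacing
        for _ in range(2000):
            c = _draw_center(rng, spec.shape, margin_vox)
            if spec.placement != "separated" or _min_pairwise_um(c, placed, g) >= min_sep:
                return c
        raise RuntimeError(
            "could not place objects with the requested separation; "
            "enlarge the volume or reduce the object count"
        )

    # --- cells (signal channel only) ---
    i = 0
    while i < spec.n_cells:
        d = max(4.0, rng.normal(spec.cell_diameter_mean, spec.cell_diameter_sd))
        if spec.placement == "clustered":
            group = min(spec.cluster_size, spec.n_cells - i)
            anchor = place_separated(d + 2 * spec.edge_width)
            centers = [anchor]
            for _ in range(group - 1):
                step = rng.normal(size=3)
                step /= np.linalg.norm(step)
                # offset slightly under one diameter so neighbouring balls fuse
                centers.append(centers[-1] + step * 0.8 * d / spacing)
            placed.append(anchor)
        else:
            centers = [place_separated(d / 2 + 2 * spec.edge_width)]
            placed.append(centers[0])
        for c in centers:
            c = np.clip(c, 1, np.array(spec.shape) - 2)
            _render_ball(signal, c, d, spec.cell_intensity, g, spec.edge_width)
            truth.cells.append(CellTruth(tuple(c), d))
            i += 1
            if i >= spec.n_cells:
                break

    # --- artefacts (both channels) ---
    for _ in range(spec.n_artefacts):
        kind = spec.artefact_kinds[rng.integers(len(spec.artefact_kinds))]
        if kind == "bright_blob":
            d = max(4.0, rng.normal(spec.cell_diameter_mean, spec.cell_diameter_sd))
            c = place_separated(d / 2 + 2 * spec.edge_width)
            for vol in (signal, autofluo):
                _render_ball(vol, c, d, spec.artefact_intensity, g, spec.edge_width)
        elif kind == "vessel_segment":
            length = rng.uniform(30.0, 60.0)
            radius = rng.integers(1, 4) * g.dx  # 1-3 in-plane voxels
            c = place_separated(length / 4)
            direction = rng.normal(size=3)
            direction[2] *= 0.3  # vessels run mostly in-plane in coronal stacks
            if np.linalg.norm(direction) < 1e-9:
                direction = np.array([1.0, 0.0, 0.0])
            for vol in (signal, autofluo):
                _render_cylinder(vol, c, direction, length, radius, spec.artefact_intensity, g, spec.edge_width)
        elif kind == "surface_debris":
            # irregular bright cluster hugging one volume face (<= 3 voxels away)
            axis = int(rng.integers(3))
            side = int(rng.integers(2))
            c = place_separated(spec.cell_diameter_mean / 2)
            face_coord = rng.uniform(0, 3) if side == 0 else spec.shape[axis] - 1 - rng.uniform(0, 3)
            c[axis] = face_coord
            for _ in range(int(rng.integers(3, 7))):
                jitter = rng.normal(scale=4.0 / spacing)  # ~4 um scatter
                blob_c = np.clip(c + jitter, 0, np.array(spec.shape) - 1)
                d = rng.uniform(4.0, 9.0)
                for vol in (signal, autofluo):
                    _render_ball(vol, blob_c, d, spec.artefact_intensity, g, spec.edge_width)
        else:  # pragma: no cover - guarded by PhantomSpec typing
            raise ValueError(f"unknown artefact kind {kind!r}")
        placed.append(c)
        truth.artefacts.append(ArtefactTruth(tuple(c), kind))

    signal_vol = PlaneStackVolume(
        np.clip(signal, 0, None).astype(np.float32), g, Channel.SIGNAL
    )
    autofluo_vol = PlaneStackVolume(
        np.clip(autofluo, 0, None).astype(np.float32), g, Channel.AUTOFLUORESCENCE
    )
    return signal_vol, autofluo_vol, truth


def downsample_axially(volume: PlaneStackVolume, factor: int) -> PlaneStackVolume:
    """Keep every Nth plane and scale dz accordingly (N = 1 is the identity).

    Retained planes are bitwise identical to the source planes; this mimics
    re-acquiring the same sample with coarser axial sampling.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"downsampling factor must be an integer >= 1, got {factor}")
    factor = int(factor)
    g = volume.geometry
    return PlaneStackVolume(
        volume.data[::factor].copy(),
        VoxelGeometry(g.dx, g.dy, g.dz * factor),
        volume.channel_id,
    )


def make_labelled_cuboid_set(
    spec: PhantomSpec, n_per_class: int
) -> list[tuple[Cuboid, int]]:
    """Balanced labelled cuboids: ``n_per_class`` cell- and artefact-centred.

    Generates a phantom containing ``n_per_class`` cells and the same number
    of cell-sized dual-channel blob artefacts (auto-enlarging the volume so
    separated placement is feasible), then extracts the classifier input
    cuboid at every true centre.  Labels are ``LABEL_CELL`` / ``LABEL_ARTEFACT``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    g = spec.geometry
    # in-plane area needed for separated placement, with generous slack
    per_object_um = 2.5 * spec.cell_diameter_mean
    side_um = per_object_um * math.ceil(math.sqrt(2 * n_per_class)) + 4 * spec.cell_diameter_mean
    nx = max(spec.shape[0], int(side_um / g.dx))
    ny = max(spec.shape[1], int(side_um / g.dy))
    nz = max(spec.shape[2], int(120.0 / g.dz))  # room for the 100 um cuboid depth
    phantom_spec = replace(
        spec,
        shape=(nx, ny, nz),
        n_cells=n_per_class,
        n_artefacts=n_per_class,
        artefact_kinds=("bright_blob",),
        placement="separated",
    )
    signal, autofluo, truth = generate_phantom(phantom_spec)
    out: list[tuple[Cuboid, int]] = []
    for cell in truth.cells:
        out.append((extract_cuboid(signal, autofluo, cell.center), LABEL_CELL))
    for art in truth.artefacts:
        out.append((extract_cuboid(signal, autofluo, art.center), LABEL_ARTEFACT))
    return out
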