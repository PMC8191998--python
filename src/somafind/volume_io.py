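"""I/O for plane-stack volumes, marker XML cell files, and detection configs.

Conventions
-----------
* A volume is an ordered stack of 2D planes (one TIFF per plane per channel);
  plane index ``k`` sits at axial position ``k * dz`` micrometres.  Plane order
  is the lexicographic sort of the (zero-padded) filenames.
* Coordinates are 0-based voxel indices: ``x`` is the in-plane column, ``y``
  the in-plane row, ``z`` the plane index.  Array storage is ``[z, y, x]``.
* Cell positions use the CellCounter marker-XML dialect for interoperability
  with existing annotation tools: ``Marker_Type`` 1 holds non-cells (artefacts,
  or unclassified candidates in a candidates-only file), ``Marker_Type`` 2
  holds cells.  Coordinates are stored as integers, rounded half-away-from-zero.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence
from xml.etree import ElementTree

import numpy as np
import tifffile
import yaml

__all__ = [
    "VoxelGeometry",
    "Channel",
    "PlaneStackVolume",
    "CellRecord",
    "read_volume",
    "write_volume",
    "read_cells_xml",
    "write_cells_xml",
    "load_config",
]

_TIFF_EXTENSIONS = {".tif", ".tiff"}


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel spacing in micrometres per axis.

    ``dz`` (plane spacing) usually differs from the in-plane spacing; the
    reference acquisition is 2 x 2 x 5 um.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"voxel spacing {name} must be finite and > 0, got {v}")

    def um_to_voxels(self, length_um: float, axis: str) -> float:
        """Convert a physical length along ``axis`` ('x'|'y'|'z') to voxels."""
        return length_um / {"x": self.dx, "y": self.dy, "z": self.dz}[axis]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cubic micrometres."""
        return self.dx * self.dy * self.dz


class Channel(str, Enum):
    SIGNAL = "signal"
    AUTOFLUORESCENCE = "autofluorescence"


@dataclass
class PlaneStackVolume:
    """A single-channel 3D volume stored as ``data[z, y, x]``."""

    data: np.ndarray
    geometry: VoxelGeometry
    channel_id: Channel = Channel.SIGNAL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 1:
            raise ValueError(f"volume must be a 3D array with >= 1 plane, got shape {self.data.shape}")

    @property
    def n_planes(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        """(n_planes, height, width) == (z, y, x) extents."""
        return self.data.shape

    def plane(self, k: int) -> np.ndarray:
        return self.data[k]

    def contains(self, x: float, y: float, z: float) -> bool:
        nz, ny, nx = self.data.shape
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz


_VALID_LABELS = ("candidate", "cell", "artefact")


@dataclass(frozen=True)
class CellRecord:
    """A point annotation: voxel-space position plus a classification label."""

    x: float
    y: float
    z: float
    label: str = "candidate"

    def __post_init__(self) -> None:
        if self.label not in _VALID_LABELS:
            raise ValueError(f"label must be one of {_VALID_LABELS}, got {self.label!r}")
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("coordinates must be finite")


def _list_plane_files(directory: Path) -> list[Path]:
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in _TIFF_EXTENSIONS and p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no TIFF planes found in {directory}")
    return files


def read_volume(
    directory: str | os.PathLike,
    channel_id: Channel | str = Channel.SIGNAL,
    geometry: VoxelGeometry | None = None,
) -> PlaneStackVolume:
    """Read a plane-stack volume from a directory of 2D TIFFs.

    Planes are ordered by lexicographic filename sort; plane ``k`` maps to
    axial position ``k * dz``.  All planes must share one shape.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"volume directory not found: {directory}")
    if geometry is None:
        geometry = VoxelGeometry(2.0, 2.0, 5.0)
    files = _list_plane_files(directory)
    planes = []
    shape = None
    for f in files:
        try:
            plane = tifffile.imread(f)
        except Exception as exc:  # pragma: no cover - depends on corrupt input
            raise OSError(f"could not read plane {f.name}: {exc}") from exc
        if plane.ndim != 2:
            raise ValueError(f"plane {f.name} is not 2D (shape {plane.shape})")
        if shape is None:
            shape = plane.shape
        elif plane.shape != shape:
            raise ValueError(
                f"inconsistent plane shape in {f.name}: {plane.shape} != {shape}"
            )
        planes.append(plane)
    return PlaneStackVolume(np.stack(planes), geometry, Channel(channel_id))


def write_volume(volume: PlaneStackVolume, directory: str | os.PathLike) -> list[Path]:
    """Write one zero-padded TIFF per plane; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(volume.n_planes - 1)))
    paths = []
    for k in range(volume.n_planes):
        path = directory / f"plane_{k:0{width}d}.tif"
        tifffile.imwrite(path, volume.data[k])
        paths.append(path)
    return paths


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


_LABEL_TO_TYPE = {"artefact": 1, "candidate": 1, "cell": 2}


def write_cells_xml(records: Sequence[CellRecord], path: str | os.PathLike) -> None:
    """Write records as CellCounter marker XML.

    ``cell`` records become ``Marker_Type`` 2; ``artefact`` and ``candidate``
    records become ``Marker_Type`` 1 (the dialect has only the two types; a
    candidates-awaiting-classification file is all type 1 by convention).
    Coordinates are rounded half-away-from-zero to integers.
    """
    root = ElementTree.Element("CellCounter_Marker_File")
    props = ElementTree.SubElement(root, "Image_Properties")
    ElementTree.SubElement(props, "Image_Filename").text = "placeholder.tif"
    data = ElementTree.SubElement(root, "Marker_Data")
    ElementTree.SubElement(data, "Current_Type").text = "1"
    for marker_type in (1, 2):
        type_el = ElementTree.SubElement(data, "Marker_Type")
        ElementTree.SubElement(type_el, "Type").text = str(marker_type)
        for rec in records:
            if _LABEL_TO_TYPE[rec.label] != marker_type:
                continue
            marker = ElementTree.SubElement(type_el, "Marker")
            ElementTree.SubElement(marker, "MarkerX").text = str(_round_half_away(rec.x))
            ElementTree.SubElement(marker, "MarkerY").text = str(_round_half_away(rec.y))
            ElementTree.SubElement(marker, "MarkerZ").text = str(_round_half_away(rec.z))
    tree = ElementTree.ElementTree(root)
    ElementTree.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def read_cells_xml(
    path: str | os.PathLike, type1_label: str = "artefact"
) -> list[CellRecord]:
    """Read a CellCounter marker XML file into CellRecords.

    ``type1_label`` chooses how ``Marker_Type`` 1 markers are labelled:
    ``"artefact"`` (default, for classified files) or ``"candidate"`` (for
    candidates-awaiting-classification files).
    """
    if type1_label not in ("artefact", "candidate"):
        raise ValueError("type1_label must be 'artefact' or 'candidate'")
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as exc:
        raise ValueError(f"malformed marker XML {path}: {exc}") from exc
    records: list[CellRecord] = []
    for type_el in tree.getroot().iter("Marker_Type"):
        type_text = type_el.findtext("Type")
        if type_text is None:
            raise ValueError(f"Marker_Type without <Type> in {path}")
        marker_type = int(type_text)
        if marker_type == 1:
            label = type1_label
        elif marker_type == 2:
            label = "cell"
        else:
            raise ValueError(f"unknown marker type {marker_type} in {path}")
        for marker in type_el.iter("Marker"):
            coords = [marker.findtext(tag) for tag in ("MarkerX", "MarkerY", "MarkerZ")]
            if any(c is None for c in coords):
                raise ValueError(f"marker missing coordinates in {path}")
            x, y, z = (float(c) for c in coords)
            records.append(CellRecord(x, y, z, label))
    return records


@dataclass
class RunPaths:
    """Channel directories declared in a detection config."""

    signal: Path
    autofluorescence: Path | None = None


def load_config(path: str | os.PathLike) -> dict:
    """Load a YAML detection config into a plain dict.

    Recognised top-level keys: ``voxel_size`` (mapping with x/y/z in um),
    ``signal_dir``, ``autofluorescence_dir``, ``detection`` (mapping of
    DetectionParameters field overrides).  Extra keys are preserved.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    if "voxel_size" in cfg:
        vs = cfg["voxel_size"]
        cfg["geometry"] = VoxelGeometry(float(vs["x"]), float(vs["y"]), float(vs["z"]))
    return cfg


def validate_channel_pair(signal: PlaneStackVolume, autofluo: PlaneStackVolume) -> None:
    """Signal and autofluorescence volumes must align voxel-for-voxel."""
    if signal.shape != autofluo.shape:
        raise ValueError(
            f"channel shape mismatch: signal {signal.shape} vs autofluorescence {autofluo.shape}"
        )
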