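"""Scoring of detections against ground truth and count-vector statistics.

Detections are matched one-to-one to true positions by greedy nearest-first
assignment within a physical radius (default: one soma diameter, 16 um).
Region-wise count vectors — e.g. algorithm vs expert counts per brain region —
are compared by the Pearson correlation coefficient and the slope of an
ordinary-least-squares best-fit line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from somafind.volume_io import CellRecord, VoxelGeometry

__all__ = [
    "MatchResult",
    "CountComparison",
    "match_detections",
    "compare_counts",
    "counts_by_region",
    "precision_recall",
]


@dataclass
class MatchResult:
    """One-to-one matching outcome between detections and truth."""

    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)
    # (detected index, truth index, distance in um)

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else float("nan")


@dataclass(frozen=True)
class CountComparison:
    pearson_r: float
    slope: float


def match_detections(
    detected: list[CellRecord],
    truth: list[CellRecord] | "object",
    radius: float = 16.0,
    geometry: VoxelGeometry | None = None,
) -> MatchResult:
    """Greedy nearest-first one-to-one matching within ``radius`` micrometres.

    ``truth`` may be a list of CellRecords or a GroundTruth object (its cells
    are used).  Candidate pairs are sorted by physical distance; each detected
    and each true position participates in at most one pair.  Counts satisfy
    TP + FN = len(truth) and TP + FP = len(detected).
    """
    if radius <= 0:
        raise ValueError("matching radius must be > 0")
    if geometry is None:
        geometry = VoxelGeometry(2.0, 2.0, 5.0)
    if hasattr(truth, "cells"):
        truth = truth.cell_records()
    scale = np.array([geometry.dx, geometry.dy, geometry.dz])
    det = np.array([[r.x, r.y, r.z] for r in detected], dtype=float).reshape(-1, 3)
    tru = np.array([[r.x, r.y, r.z] for r in truth], dtype=float).reshape(-1, 3)

    pairs: list[tuple[int, int, float]] = []
    if len(det) and len(tru):
        diff = (det[:, None, :] - tru[None, :, :]) * scale
        dist = np.linalg.norm(diff, axis=2)
        di, ti = np.nonzero(dist <= radius)
        order = np.argsort(dist[di, ti], kind="stable")
        used_det: set[int] = set()
        used_tru: set[int] = set()
        for k in order:
            d, t = int(di[k]), int(ti[k])
            if d in used_det or t in used_tru:
                continue
            used_det.add(d)
            used_tru.add(t)
            pairs.append((d, t, float(dist[d, t])))
    tp = len(pairs)
    return MatchResult(
        true_positives=tp,
        false_positives=len(det) - tp,
        false_negatives=len(tru) - tp,
        pairs=pairs,
    )


def precision_recall(match: MatchResult) -> tuple[float, float]:
    return match.precision, match.recall


def compare_counts(
    counts_a: np.ndarray, counts_b: np.ndarray, through_origin: bool = False
) -> CountComparison:
    """Pearson r and OLS best-fit slope of ``b`` regressed on ``a``.

    By default the intercept is fitted; ``through_origin=True`` constrains the
    line through zero (slope = sum(ab) / sum(a^2)).  Both vectors must have at
    least two entries and nonzero variance.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("count vectors must be equal-length 1D with >= 2 entries")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("count vectors must have nonzero variance")
    r = float(stats.pearsonr(a, b).statistic)
    if through_origin:
        slope = float(np.sum(a * b) / np.sum(a * a))
    else:
        slope = float(stats.linregress(a, b).slope)
    return CountComparison(pearson_r=r, slope=slope)


def counts_by_region(
    cells: list[CellRecord], region_mask: np.ndarray
) -> np.ndarray:
    """Cells per region label in a ``[z, y, x]`` integer label volume.

    A cell is assigned the label at its coordinate rounded to the nearest
    voxel.  Label 0 means unassigned and is excluded; the returned vector has
    one entry per label 1..max(label).  Cells outside the mask raise.
    """
    region_mask = np.asarray(region_mask)
    n_labels = int(region_mask.max())
    counts = np.zeros(n_labels, dtype=np.int64)
    nz, ny, nx = region_mask.shape
    for rec in cells:
        x, y, z = (int(round(v)) for v in (rec.x, rec.y, rec.z))
        if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
            raise ValueError(f"cell at ({rec.x}, {rec.y}, {rec.z}) outside mask bounds")
        label = int(region_mask[z, y, x])
        if label > 0:
            counts[label - 1] += 1
    return counts
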