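"""Candidate detector: filtering, thresholding, overlap filter, merge/split.

Oracles used here are deliberately independent of the implementation:
per-voxel python loops for the overlap fraction, a BFS flood fill for
connected components, and direct enumeration for the ellipsoid footprint.
"""

import numpy as np
import pytest

from somafind.candidate_detection import (
    CandidateCluster,
    DetectionParameters,
    detect_candidates,
    ellipsoid_footprint,
    filter_plane,
    is_too_large,
    merge_structures,
    overlap_filter,
    split_cluster,
    threshold_plane,
)
from somafind.synthetic_data import PhantomSpec, generate_phantom
from somafind.volume_io import CellRecord, PlaneStackVolume, VoxelGeometry

GEOM = VoxelGeometry(2.0, 2.0, 5.0)
PARAMS = DetectionParameters()


# --------------------------------------------------------------- oracles
def brute_force_overlap(mask: np.ndarray, offsets: np.ndarray, frac: float) -> np.ndarray:
    """Exhaustive per-voxel fraction computation (out-of-bounds = false)."""
    nz, ny, nx = mask.shape
    out = np.zeros_like(mask, dtype=bool)
    k_total = len(offsets)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                hits = 0
                for i, j, k in offsets:
                    zz, yy, xx = z + k, y + j, x + i
                    if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and mask[zz, yy, xx]:
                        hits += 1
                out[z, y, x] = hits / k_total >= frac - 1e-9
    return out


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """Independent 26-connectivity flood fill returning voxel sets."""
    nz, ny, nx = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for z0 in range(nz):
        for y0 in range(ny):
            for x0 in range(nx):
                if not mask[z0, y0, x0] or seen[z0, y0, x0]:
                    continue
                stack = [(z0, y0, x0)]
                seen[z0, y0, x0] = True
                comp = set()
                while stack:
                    z, y, x = stack.pop()
                    comp.add((z, y, x))
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                zz, yy, xx = z + dz, y + dy, x + dx
                                if (
                                    0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx
                                    and mask[zz, yy, xx] and not seen[zz, yy, xx]
                                ):
                                    seen[zz, yy, xx] = True
                                    stack.append((zz, yy, xx))
                components.append(comp)
    return components


def digitized_ball(shape_zyx, centers_xyz, radius_um, geometry=GEOM) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape_zyx], indexing="ij")
    mask = np.zeros(shape_zyx, bool)
    for cx, cy, cz in centers_xyz:
        mask |= (
            ((xx - cx) * geometry.dx / radius_um) ** 2
            + ((yy - cy) * geometry.dy / radius_um) ** 2
            + ((zz - cz) * geometry.dz / radius_um) ** 2
            <= 1
        )
    return mask


# --------------------------------------------------------------- filtering
class TestFilterPlane:
    def test_constant_plane_gives_constant_response(self):
        out = filter_plane(np.full((40, 40), 37.0), PARAMS, GEOM)
        assert np.allclose(out, out.flat[0], atol=1e-10)

    def test_response_peaks_at_gaussian_blob_center(self):
        yy, xx = np.mgrid[:60, :60]
        sigma = 0.2 * PARAMS.soma_diameter / GEOM.dx
        plane = 100 * np.exp(-(((xx - 30) ** 2 + (yy - 25) ** 2) / (2 * sigma**2)))
        out = filter_plane(plane, PARAMS, GEOM)
        peak = np.unravel_index(np.argmax(out), out.shape)  # brute-force scan
        assert abs(peak[0] - 25) <= 1 and abs(peak[1] - 30) <= 1

    def test_median_filter_suppresses_isolated_hot_voxels(self):
        salt = np.zeros((40, 40))
        salt[20, 20] = 1000.0
        blob = np.zeros((40, 40))
        blob[19:22, 19:22] = 1000.0
        assert filter_plane(blob, PARAMS, GEOM).max() > filter_plane(salt, PARAMS, GEOM).max()

    def test_nonfinite_input_rejected(self):
        plane = np.ones((10, 10))
        plane[3, 3] = np.nan
        with pytest.raises(ValueError):
            filter_plane(plane, PARAMS, GEOM)


class TestThresholdPlane:
    def test_hand_computed_population_statistics(self):
        plane = np.array([[0.0, 0.0, 0.0, 0.0, 100.0]])
        # mean 20, population SD 40 -> threshold at 60 -> only the 100 passes
        mask = threshold_plane(plane, 1.0)
        assert mask.sum() == 1 and mask[0, 4]

    def test_constant_plane_yields_empty_mask(self):
        assert not threshold_plane(np.full((5, 5), 3.0), 10.0).any()

    def test_zero_multiplier_reduces_to_mean_threshold(self):
        rng = np.random.default_rng(0)
        plane = rng.normal(size=(20, 20))
        np.testing.assert_array_equal(threshold_plane(plane, 0.0), plane > plane.mean())

    def test_lower_multiplier_never_decreases_voxel_count(self):
        rng = np.random.default_rng(1)
        plane = rng.normal(size=(30, 30))
        counts = [threshold_plane(plane, m).sum() for m in (10.0, 5.0, 2.0, 0.5)]
        assert counts == sorted(counts)


# --------------------------------------------------------------- footprint
class TestEllipsoidFootprint:
    @pytest.mark.parametrize(
        "lateral,axial,geom",
        [(6.0, 15.0, GEOM), (2.0, 2.0, VoxelGeometry(1, 1, 1)), (8.0, 20.0, GEOM)],
    )
    def test_matches_direct_enumeration(self, lateral, axial, geom):
        offsets = {tuple(o) for o in ellipsoid_footprint(lateral, axial, geom)}
        a, c = lateral / 2, axial / 2
        expected = set()
        for i in range(-10, 11):
            for j in range(-10, 11):
                for k in range(-10, 11):
                    if (i * geom.dx / a) ** 2 + (j * geom.dy / a) ** 2 + (k * geom.dz / c) ** 2 <= 1 + 1e-12:
                        expected.add((i, j, k))
        assert offsets == expected

    def test_reference_footprint_contains_origin_and_face_neighbours(self):
        offsets = {tuple(o) for o in ellipsoid_footprint(6.0, 15.0, GEOM)}
        for o in [(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
            assert o in offsets

    def test_isotropic_2um_widths_give_seven_voxel_cross(self):
        offsets = {tuple(o) for o in ellipsoid_footprint(2.0, 2.0, VoxelGeometry(1, 1, 1))}
        assert offsets == {(0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)}

    def test_symmetric_under_axis_swap_when_isotropic_in_plane(self):
        offsets = ellipsoid_footprint(6.0, 15.0, GEOM)
        swapped = {(j, i, k) for i, j, k in map(tuple, offsets)}
        assert swapped == {tuple(o) for o in offsets}

    def test_subvoxel_width_rejected(self):
        with pytest.raises(ValueError, match="axial"):
            ellipsoid_footprint(6.0, 4.0, GEOM)  # 4 um < 5 um plane spacing


# --------------------------------------------------------------- overlap
class TestOverlapFilter:
    def test_full_mask_true_wherever_footprint_fits_inside(self):
        mask = np.ones((7, 9, 9), bool)
        offsets = ellipsoid_footprint(6.0, 15.0, GEOM)
        out = overlap_filter(mask, offsets, 1.0)
        assert out[1:-1, 1:-1, 1:-1].all()
        assert not out[0, 0, 0]  # corner loses out-of-bounds offsets

    def test_isolated_voxel_cannot_reach_majority_overlap(self):
        mask = np.zeros((7, 9, 9), bool)
        mask[3, 4, 4] = True
        offsets = ellipsoid_footprint(2.0, 2.0, VoxelGeometry(1, 1, 1))
        assert not overlap_filter(mask, offsets, 0.6).any()  # 1/7 < 0.6

    def test_solid_ball_passes_at_its_center(self):
        mask = digitized_ball((13, 13, 13), [(6, 6, 6)], 8.0, VoxelGeometry(1, 1, 1))
        offsets = ellipsoid_footprint(6.0, 6.0, VoxelGeometry(1, 1, 1))
        out = overlap_filter(mask, offsets, 0.6)
        assert out[6, 6, 6]
        assert brute_force_overlap(mask, offsets, 0.6)[6, 6, 6]

    @pytest.mark.parametrize("seed", range(8))
    def test_equals_exhaustive_fraction_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((6, 10, 10)) < 0.35
        offsets = ellipsoid_footprint(6.0, 15.0, GEOM)
        np.testing.assert_array_equal(
            overlap_filter(mask, offsets, 0.6), brute_force_overlap(mask, offsets, 0.6)
        )

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError):
            overlap_filter(np.zeros((3, 3, 3), bool), np.empty((0, 3), int), 0.5)


# --------------------------------------------------------------- merging
class TestMergeStructures:
    def test_face_adjacent_voxels_merge(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = mask[1, 1, 2] = True
        assert len(merge_structures(mask)) == 1

    def test_well_separated_voxels_stay_apart(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[1, 1, 1] = mask[5, 5, 5] = True
        assert len(merge_structures(mask)) == 2

    def test_empty_mask_gives_empty_list(self):
        assert merge_structures(np.zeros((3, 3, 3), bool)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_flood_fill_oracle_on_random_masks(self, seed):
        rng = np.random.default_rng(100 + seed)
        mask = rng.random((8, 12, 12)) < 0.2
        clusters = merge_structures(mask)
        oracle = flood_fill_components(mask)
        assert len(clusters) == len(oracle)
        cluster_sets = {frozenset((z, y, x) for x, y, z in map(tuple, c.voxels)) for c in clusters}
        assert cluster_sets == {frozenset(c) for c in oracle}


# --------------------------------------------------------------- splitting
class TestSplitting:
    def test_single_voxel_is_not_too_large(self):
        assert not is_too_large(CandidateCluster(np.array([[1, 1, 1]])), PARAMS, GEOM)

    def test_soma_sized_ball_is_not_too_large(self):
        mask = digitized_ball((20, 20, 20), [(10, 10, 10)], PARAMS.soma_diameter / 2)
        (cluster,) = merge_structures(mask)
        assert not is_too_large(cluster, PARAMS, GEOM)

    def test_double_diameter_ball_is_too_large(self):
        mask = digitized_ball((24, 40, 40), [(20, 20, 12)], PARAMS.soma_diameter)
        (cluster,) = merge_structures(mask)
        assert is_too_large(cluster, PARAMS, GEOM)

    def test_lone_soma_ball_returned_unsplit_with_true_centroid(self):
        mask = digitized_ball((20, 30, 30), [(15, 15, 10)], 8.0)
        (cluster,) = merge_structures(mask)
        out = split_cluster(cluster, PARAMS, GEOM)
        assert len(out) == 1
        np.testing.assert_allclose(out[0].centroid, [15, 15, 10], atol=0.5)

    @pytest.mark.parametrize(
        "centers",
        [
            [(20, 20, 10), (28, 20, 10)],
            [(16, 20, 10), (24, 20, 10), (32, 20, 10)],
        ],
    )
    def test_fused_somata_split_into_constituents(self, centers):
        mask = digitized_ball((20, 40, 48), centers, 8.0)
        (cluster,) = merge_structures(mask)
        assert is_too_large(cluster, PARAMS, GEOM)
        out = split_cluster(cluster, PARAMS, GEOM)
        assert len(out) == len(centers)
        got = sorted(tuple(c.centroid) for c in out)
        for (gx, gy, gz), (cx, cy, cz) in zip(got, sorted(centers)):
            assert abs(gx - cx) <= 2 and abs(gy - cy) <= 2 and abs(gz - cz) <= 2
        lo = cluster.voxels.min(axis=0)
        hi = cluster.voxels.max(axis=0)
        for c in out:
            assert np.all(c.centroid >= lo - 1e-9) and np.all(c.centroid <= hi + 1e-9)


# --------------------------------------------------------------- end to end
class TestDetectCandidates:
    def test_all_zero_volume_yields_no_candidates(self):
        vol = PlaneStackVolume(np.zeros((8, 40, 40)), GEOM)
        assert detect_candidates(vol) == []

    def test_detection_is_deterministic(self):
        spec = PhantomSpec(shape=(96, 96, 24), n_cells=5, seed=3)
        signal, _, _ = generate_phantom(spec)
        a = detect_candidates(signal)
        b = detect_candidates(signal)
        assert len(a) == len(b)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.voxels, cb.voxels)

    def test_centroid_of_symmetric_ball_matches_construction_center(self):
        mask = digitized_ball((20, 30, 30), [(15, 15, 10)], 8.0)
        (cluster,) = merge_structures(mask)
        np.testing.assert_allclose(cluster.centroid, [15, 15, 10], atol=0.5)
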