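import warnings
from collections import deque

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from aneucad.phantom import PhantomSpec, generate_phantom
from aneucad.segment import (
    RegionGrowParams,
    SeedPointSet,
    binarize_foreground,
    coverage_fraction,
    dilate_voi,
    estimate_vessel_model,
    extract_mesh,
    grow_region,
    segment_vessels,
    select_skull_seeds,
    select_vessel_seeds,
    sphere_offsets,
    strip_skull,
)
from aneucad.volume_io import Volume


def flood_fill_oracle(data, seeds, lo, hi, connectivity=26):
    """Brute-force BFS flood fill, independent of the implementation."""
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
        and {6: abs(dz) + abs(dy) + abs(dx) == 1,
             18: abs(dz) + abs(dy) + abs(dx) <= 2,
             26: True}[connectivity]
    ]
    mask = np.zeros(data.shape, dtype=bool)
    q = deque(p for p in seeds if lo <= data[p] <= hi)
    for p in q:
        mask[p] = True
    while q:
        z, y, x = q.popleft()
        for dz, dy, dx in offsets:
            n = (z + dz, y + dy, x + dx)
            if all(0 <= c < s for c, s in zip(n, data.shape)):
                if not mask[n] and lo <= data[n] <= hi:
                    mask[n] = True
                    q.append(n)
    return mask


class TestSkullSeeds:
    def test_bright_sphere_contact_distance(self):
        n = 64
        zz, yy, xx = np.indices((n, n, n))
        c = (n - 1) / 2
        dist = np.sqrt((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
        data = np.where(dist <= 10, 500.0, 0.0)
        seeds = select_skull_seeds(Volume(data), 250.0)
        assert len(seeds) == 6
        for p in seeds.points:
            d = np.linalg.norm(np.asarray(p) - c)
            assert d == pytest.approx(10, abs=1.0)
            assert data[p] >= 250.0

    def test_all_zero_volume_errors(self):
        with pytest.raises(ValueError, match="no skull contact"):
            select_skull_seeds(Volume(np.zeros((16, 16, 16))), 1.0)

    def test_shell_touching_only_top_region(self):
        data = np.zeros((32, 32, 32))
        data[2:4, 10:22, 10:22] = 800.0  # plate near the z- face only
        seeds = select_skull_seeds(Volume(data), 400.0)
        assert 1 <= len(seeds) <= 6
        by_face = dict(zip(seeds.sources, seeds.points))
        assert "z-" in by_face
        assert 2 <= by_face["z-"][0] <= 3


class TestGrowRegion:
    def test_uniform_block_fills_exactly(self):
        data = np.zeros((9, 9, 9))
        data[2:7, 2:7, 2:7] = 100.0
        mask = grow_region(Volume(data), SeedPointSet([(4, 4, 4)], "test"),
                           RegionGrowParams(50, 150))
        assert mask.sum() == 125
        assert mask[2:7, 2:7, 2:7].all()

    def test_out_of_range_seed_errors(self):
        data = np.zeros((5, 5, 5))
        with pytest.raises(ValueError, match="all seeds"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grow_region(Volume(data), SeedPointSet([(2, 2, 2)], "test"),
                            RegionGrowParams(50, 150))

    def test_disconnected_block_not_grown(self):
        data = np.zeros((10, 10, 10))
        data[1:3, 1:3, 1:3] = 100.0
        data[6:9, 6:9, 6:9] = 100.0
        mask = grow_region(Volume(data), SeedPointSet([(1, 1, 1)], "test"),
                           RegionGrowParams(50, 150))
        assert mask[1:3, 1:3, 1:3].all()
        assert not mask[6:9, 6:9, 6:9].any()

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        data=hnp.arrays(np.float64, (6, 6, 6), elements=st.floats(0, 9)),
        seed=st.tuples(*[st.integers(0, 5)] * 3),
    )
    def test_mask_stays_in_band_and_contains_seed(self, data, seed):
        data = data.copy()
        data[seed] = 5.0
        mask = grow_region(Volume(data), SeedPointSet([seed], "test"),
                           RegionGrowParams(3.0, 7.0))
        assert mask[seed]
        vals = data[mask]
        assert vals.min() >= 3.0 and vals.max() <= 7.0

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_flood_fill(self, connectivity):
        rng = np.random.default_rng(99)
        for _ in range(20):
            data = rng.integers(0, 10, (10, 10, 10)).astype(float)
            seed = tuple(rng.integers(0, 10, 3))
            lo, hi = 3.0, 7.0
            if not lo <= data[seed] <= hi:
                data[seed] = 5.0
            got = grow_region(Volume(data), SeedPointSet([seed], "test"),
                              RegionGrowParams(lo, hi, connectivity))
            want = flood_fill_oracle(data, [seed], lo, hi, connectivity)
            np.testing.assert_array_equal(got, want)


class TestStripSkull:
    def test_shell_removed_tube_untouched(self, segmented_phantom):
        lab = segmented_phantom["lab"]
        pre = segmented_phantom["pre"]
        stripped = segmented_phantom["stripped"]
        vessel = lab.labels >= 1
        np.testing.assert_array_equal(stripped.data[vessel], pre.data[vessel])
        assert stripped.data.max() < pre.data.max()

    def test_no_shell_errors(self):
        data = np.zeros((32, 32, 32))
        data[4:8, 4:8, 4:8] = 100.0  # off the face-centre rays, nothing peripheral
        with pytest.raises(ValueError, match="no skull contact"):
            strip_skull(Volume(data), contact_threshold=90.0, lower_fraction=0.3)

    def test_returns_mask_covering_shell(self, segmented_phantom):
        pre = segmented_phantom["pre"]
        stripped, mask = strip_skull(pre)
        assert mask.any()
        assert (stripped.data[mask] == stripped.data.min()).all()


class TestBinarize:
    def test_strictly_greater(self):
        data = np.array([0.0, 10.0, 20.0]).reshape(1, 1, 3)
        mask = binarize_foreground(Volume(data), 10.0)
        np.testing.assert_array_equal(mask.ravel(), [False, False, True])

    def test_threshold_at_max_gives_empty(self, rng):
        v = Volume(rng.random((4, 4, 4)))
        assert not binarize_foreground(v, float(v.data.max())).any()

    def test_threshold_below_min_gives_full(self, rng):
        v = Volume(rng.random((4, 4, 4)))
        assert binarize_foreground(v, float(v.data.min()) - 1).all()


class TestVesselSeeds:
    def _components(self, sizes, n=40):
        """Disjoint cubes of given voxel counts (must be perfect cubes)."""
        data = np.zeros((n, n, n))
        mask = np.zeros((n, n, n), dtype=bool)
        pos = 1
        for i, s in enumerate(sizes):
            side = round(s ** (1 / 3))
            assert side**3 == s
            mask[pos:pos + side, 1:1 + side, 1:1 + side] = True
            data[pos:pos + side, 1:1 + side, 1:1 + side] = 100 + i
            pos += side + 2
        return mask, Volume(data)

    def test_top_five_of_seven(self):
        sizes = [125, 64, 27, 8, 1, 1, 1]
        mask, v = self._components(sizes, n=50)
        seeds, union = select_vessel_seeds(mask, v)
        assert len(seeds) == 5
        assert union.sum() == 125 + 64 + 27 + 8 + 1

    def test_fewer_components_than_five(self):
        mask, v = self._components([27, 8, 1], n=30)
        seeds, _ = select_vessel_seeds(mask, v)
        assert len(seeds) == 3

    def test_deterministic_under_ties(self):
        mask = np.zeros((12, 12, 12), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        mask[8:10, 8:10, 8:10] = True  # same size
        v = Volume(np.ones((12, 12, 12)))
        a, _ = select_vessel_seeds(mask, v)
        b, _ = select_vessel_seeds(mask, v)
        assert a.points == b.points
        # tie broken toward the smaller lexicographic centroid
        assert a.sources[0] == "rank-1" and a.points[0][0] <= 3

    def test_seed_is_component_max_intensity_voxel(self, rng):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[2:6, 2:6, 2:6] = True
        data = rng.random((10, 10, 10))
        data[4, 3, 5] = 99.0
        seeds, _ = select_vessel_seeds(mask, Volume(data))
        assert seeds.points[0] == (4, 3, 5)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            select_vessel_seeds(np.zeros((4, 4, 4), bool), Volume(np.zeros((4, 4, 4))))


class TestVesselModel:
    def test_two_point_sample(self):
        data = np.zeros((1, 1, 2))
        data[0, 0] = [90.0, 110.0]
        m = estimate_vessel_model(Volume(data), np.ones((1, 1, 2), bool))
        assert m.mu == pytest.approx(100.0)
        assert m.sigma == pytest.approx(np.sqrt(200.0), rel=1e-6)  # 14.142...
        assert m.n == 2

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(42)
        data = rng.normal(300, 20, (22, 22, 22))  # > 10^4 voxels
        m = estimate_vessel_model(Volume(data), np.ones(data.shape, bool))
        assert m.mu == pytest.approx(300, abs=1.0)
        assert m.sigma == pytest.approx(20, abs=1.0)

    def test_single_voxel_errors(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        with pytest.raises(ValueError):
            estimate_vessel_model(Volume(np.ones((3, 3, 3))), mask)

    def test_degenerate_sample_floors_sigma_with_warning(self):
        mask = np.ones((2, 2, 2), bool)
        with pytest.warns(UserWarning, match="sigma"):
            m = estimate_vessel_model(Volume(np.full((2, 2, 2), 7.0)), mask)
        assert m.sigma > 0


class TestSegmentVessels:
    def test_phantom_tube_recall(self, segmented_phantom):
        stripped = segmented_phantom["stripped"]
        lab = segmented_phantom["lab"]
        mask = segmented_phantom["vessel_mask"]
        model = segmented_phantom["model"]
        lo, hi = model.band
        in_band = (lab.labels >= 1) & (stripped.data >= lo) & (stripped.data <= hi)
        recall = (mask & in_band).sum() / in_band.sum()
        assert recall >= 0.9

    def test_output_intensities_inside_band(self, segmented_phantom):
        stripped = segmented_phantom["stripped"]
        mask = segmented_phantom["vessel_mask"]
        lo, hi = segmented_phantom["model"].band
        vals = stripped.data[mask]
        assert vals.min() >= lo and vals.max() <= hi

    def test_constant_tube_floors_sigma_and_keeps_tube(self):
        data = np.zeros((24, 24, 24))
        data[10:14, 4:20, 10:14] = 300.0
        with pytest.warns(UserWarning, match="sigma"):
            mask, model = segment_vessels(Volume(data), background_value=100.0)
        np.testing.assert_array_equal(mask, data == 300.0)

    def test_empty_foreground_errors(self):
        v = Volume(np.zeros((8, 8, 8)))
        with pytest.raises(ValueError):
            segment_vessels(v, background_value=10.0)


class TestMeshExtraction:
    def test_single_voxel_closed_surface(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        mesh = extract_mesh(mask, (1.0, 1.0, 1.0))
        assert mesh.euler_characteristic() == 2
        assert mesh.is_watertight()

    def test_ball_area_close_to_analytic(self):
        r = 8
        zz, yy, xx = np.mgrid[-10:11, -10:11, -10:11]
        ball = zz**2 + yy**2 + xx**2 <= r * r
        mesh = extract_mesh(ball, (1.0, 1.0, 1.0))
        assert mesh.area() == pytest.approx(4 * np.pi * r * r, rel=0.15)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError):
            extract_mesh(np.zeros((4, 4, 4), bool), (1, 1, 1))

    def test_vertices_in_world_coordinates(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        mesh = extract_mesh(mask, (2.0, 2.0, 2.0), origin=(10.0, 0.0, 0.0))
        center = mesh.vertices.mean(axis=0)
        np.testing.assert_allclose(center, [12.0, 2.0, 2.0], atol=1e-6)


class TestVOI:
    def test_single_voxel_dilation_counts_lattice_ball(self):
        # independent enumeration of the lattice ball
        r = 10
        count = 0
        for dz in range(-r, r + 1):
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dz * dz + dy * dy + dx * dx <= r * r:
                        count += 1
        mask = np.zeros((25, 25, 25), bool)
        mask[12, 12, 12] = True
        voi = dilate_voi(mask, radius=10)
        assert voi.mask.sum() == count == sphere_offsets(10)

    def test_radius_zero_is_identity(self, rng):
        mask = rng.random((8, 8, 8)) > 0.7
        voi = dilate_voi(mask, radius=0)
        np.testing.assert_array_equal(voi.mask, mask)

    def test_dilation_nesting(self, rng):
        mask = np.zeros((20, 20, 20), bool)
        mask[10, 10, 10] = True
        small_then = dilate_voi(dilate_voi(mask, 3).mask, 4).mask
        big = dilate_voi(mask, 7).mask
        assert (small_then <= big).all()

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate_voi(np.ones((2, 2, 2), bool), radius=-1)

    def test_voi_contains_source_mask(self, rng):
        mask = rng.random((10, 10, 10)) > 0.8
        voi = dilate_voi(mask, 2)
        assert (voi.mask | ~mask).all()


class TestCoverage:
    def test_full_inside(self):
        voi = dilate_voi(np.ones((4, 4, 4), bool), 0)
        ane = np.zeros((4, 4, 4), bool)
        ane[1, 1, 1] = True
        assert coverage_fraction(voi, ane) == 1.0

    def test_disjoint(self):
        m = np.zeros((4, 4, 4), bool)
        m[0, 0, 0] = True
        voi = dilate_voi(m, 0)
        ane = np.zeros((4, 4, 4), bool)
        ane[3, 3, 3] = True
        assert coverage_fraction(voi, ane) == 0.0

    def test_partial_fraction(self):
        m = np.zeros((1, 1, 10), bool)
        m[0, 0, :3] = True
        voi = dilate_voi(m, 0)
        ane = np.ones((1, 1, 10), bool)
        assert coverage_fraction(voi, ane) == pytest.approx(0.3)

    def test_empty_aneurysm_errors(self):
        voi = dilate_voi(np.ones((2, 2, 2), bool), 0)
        with pytest.raises(ValueError):
            coverage_fraction(voi, np.zeros((2, 2, 2), bool))
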