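"""Core thresholding, component filtering and lesion summarization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stirquant import (
    GridMismatchError,
    ReferenceROI,
    RegionMask,
    ThresholdSpec,
    compute_threshold,
    filter_small,
    label_components,
    mask_hyperintense,
    quantify_image_set,
    relative_intensity,
    roi_stats,
    summarize,
)
from stirquant.quantify import PRESET_K, ROIStats
from .conftest import make_volume


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def union_find_components(mask, connectivity):
    """Brute-force connected components via union-find."""
    offsets = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            for ds in (-1, 0, 1):
                if (dr, dc, ds) == (0, 0, 0):
                    continue
                order = abs(dr) + abs(dc) + abs(ds)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dr, dc, ds))
    coords = list(map(tuple, np.argwhere(mask)))
    parent = {c: c for c in coords}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    on = set(coords)
    for (r, c, s) in coords:
        for dr, dc, ds in offsets:
            nb = (r + dr, c + dc, s + ds)
            if nb in on:
                ra, rb = find((r, c, s)), find(nb)
                if ra != rb:
                    parent[ra] = rb
    groups = {}
    for c in coords:
        groups.setdefault(find(c), set()).add(c)
    return set(frozenset(g) for g in groups.values())


def percentile_oracle(values, p):
    """Linear interpolation between order statistics at rank p*(n-1)+1."""
    xs = sorted(values)
    h = (p / 100.0) * (len(xs) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


# ---------------------------------------------------------------------------
# ROI statistics and threshold
# ---------------------------------------------------------------------------

class TestRoiStats:
    def test_constant_roi(self):
        vox = np.full((20, 20, 2), 100.0)
        roi = ReferenceROI(np.array([[r, c, 0] for r in range(20) for c in range(10)]))
        stats = roi_stats(make_volume(vox), roi)
        assert (stats.mean, stats.sd, stats.n) == (100.0, 0.0, 200)

    def test_two_point_sd_uses_n_minus_1(self):
        vox = np.zeros((2, 1, 1))
        vox[0, 0, 0], vox[1, 0, 0] = 90.0, 110.0
        roi = ReferenceROI(np.array([[0, 0, 0], [1, 0, 0]]))
        with pytest.warns(UserWarning, match="200"):
            stats = roi_stats(make_volume(vox), roi)
        assert stats.mean == pytest.approx(100.0)
        assert stats.sd == pytest.approx(20.0 / np.sqrt(2))  # |110-90|/sqrt(2)
        assert stats.n == 2

    def test_matches_two_pass_oracle(self, rng):
        vox = rng.gamma(4.0, 25.0, (10, 10, 3))
        coords = np.array([[r, c, s] for r in range(10) for c in range(10)
                           for s in range(3)])
        stats = roi_stats(make_volume(vox), ReferenceROI(coords))
        flat = vox.ravel()
        mean = sum(flat) / len(flat)
        sd = (sum((v - mean) ** 2 for v in flat) / (len(flat) - 1)) ** 0.5
        assert stats.mean == pytest.approx(mean, rel=1e-10)
        assert stats.sd == pytest.approx(sd, rel=1e-10)

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError):
            roi_stats(make_volume(np.zeros((2, 2, 2))),
                      ReferenceROI(np.empty((0, 3), dtype=int)))

    def test_out_of_bounds_roi_is_error(self):
        with pytest.raises(GridMismatchError):
            roi_stats(make_volume(np.zeros((2, 2, 2))),
                      ReferenceROI(np.array([[5, 0, 0]])))


class TestThreshold:
    @pytest.mark.parametrize("mean,sd,k,expected", [
        (100.0, 10.0, 4.15, 141.5),   # spine preset multiplier
        (100.0, 10.0, 0.0, 100.0),
        (50.0, 20.0, 2.64, 102.8),    # SI preset multiplier
    ])
    def test_mean_plus_k_sd(self, mean, sd, k, expected):
        assert compute_threshold(mean, sd, k) == pytest.approx(expected)

    def test_negative_arguments_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(100, -1, 4.15)
        with pytest.raises(ValueError):
            compute_threshold(100, 1, -0.5)

    def test_presets(self):
        assert ThresholdSpec.from_preset("spine").k == 4.15
        assert ThresholdSpec.from_preset("si").k == 2.64
        with pytest.raises(ValueError):
            ThresholdSpec.from_preset("knee")


class TestMaskHyperintense:
    def test_strict_inequality_at_boundary(self):
        vox = np.zeros((5, 1, 1))
        vox[:, 0, 0] = [100.0, 141.5, 141.6, 200.0, 90.0]
        bone = RegionMask(np.ones((5, 1, 1), dtype=bool))
        mask = mask_hyperintense(make_volume(vox), bone, 141.5)
        assert mask.n_voxels == 2  # 141.5 itself is excluded

    def test_threshold_extremes(self, rng):
        vox = rng.uniform(10, 20, (4, 4, 4))
        bone = RegionMask(rng.random((4, 4, 4)) > 0.4)
        low = mask_hyperintense(make_volume(vox), bone, 5.0)
        np.testing.assert_array_equal(low.voxels, bone.voxels)
        high = mask_hyperintense(make_volume(vox), bone, 25.0)
        assert high.n_voxels == 0

    def test_grid_mismatch(self):
        with pytest.raises(GridMismatchError):
            mask_hyperintense(make_volume(np.zeros((2, 2, 2))),
                              RegionMask(np.ones((3, 3, 3), dtype=bool)), 0.0)


class TestComponents:
    def test_isolated_voxels_are_separate(self):
        m = np.zeros((5, 5, 5), dtype=bool)
        m[0, 0, 0] = m[4, 4, 4] = True
        assert len(label_components(RegionMask(m), 26)) == 2

    def test_corner_touch_depends_on_connectivity(self):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True  # touch only at the corner
        assert len(label_components(RegionMask(m), 26)) == 1
        assert len(label_components(RegionMask(m), 6)) == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_union_find_oracle(self, connectivity, rng):
        m = rng.random((20, 20, 10)) < 0.2
        comps = label_components(RegionMask(m), connectivity)
        got = set(frozenset(map(tuple, c)) for c in comps)
        assert got == union_find_components(m, connectivity)

    def test_per_slice_2d_mode_never_bridges_slices(self):
        m = np.zeros((3, 3, 2), dtype=bool)
        m[1, 1, 0] = m[1, 1, 1] = True  # stacked across slices
        assert len(label_components(RegionMask(m), 26)) == 1
        assert len(label_components(RegionMask(m), 8)) == 2
        assert len(label_components(RegionMask(m), 4)) == 2

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_components(RegionMask(np.zeros((2, 2, 2), dtype=bool)), 5)


class TestFilterSmall:
    def test_ten_voxel_object_survives_nine_does_not(self):
        comps = [np.zeros((n, 3), dtype=int) for n in (9, 10, 3, 25)]
        kept = filter_small(comps, min_size=10)
        assert sorted(len(c) for c in kept) == [10, 25]

    def test_empty_and_identity(self):
        assert filter_small([], 10) == []
        comps = [np.zeros((1, 3), dtype=int)]
        assert len(filter_small(comps, min_size=1)) == 1


class TestRelativeIntensity:
    @pytest.mark.parametrize("s,mean,expected", [
        (100.0, 100.0, 0.0),
        (200.0, 100.0, 1.0),
        (150.0, 100.0, 0.5),
    ])
    def test_normalization(self, s, mean, expected):
        assert relative_intensity(s, mean) == pytest.approx(expected)

    def test_nonpositive_mean_is_error(self):
        with pytest.raises(ValueError):
            relative_intensity(100.0, 0.0)


class TestSummarize:
    def _stats(self):
        return ROIStats(mean=100.0, sd=10.0, n=200)

    def test_volume_and_count(self):
        vox = np.full((10, 10, 10), 150.0)
        coords = np.argwhere(np.ones((10, 10, 5), dtype=bool))
        res = summarize([coords[:500]], make_volume(vox), self._stats(),
                        141.5, 4.15, 0.004)
        assert res.volume_hyper_cm3 == pytest.approx(2.0)
        assert res.n_objects == 1
        assert res.s_rel_mean == pytest.approx(0.5)

    def test_pooled_not_per_lesion_means(self):
        vox = np.zeros((4, 1, 1))
        vox[:, 0, 0] = [120.0, 140.0, 160.0, 180.0]  # S_rel 0.2 0.4 0.6 0.8
        comps = [np.array([[0, 0, 0]]), np.array([[1, 0, 0], [2, 0, 0], [3, 0, 0]])]
        res = summarize(comps, make_volume(vox), self._stats(), 110.0, 1.0, 0.004)
        assert res.s_rel_mean == pytest.approx(0.5)
        assert res.s_rel_median == pytest.approx(0.5)

    def test_percentiles_match_sorting_oracle(self, rng):
        n = 1000
        vals = rng.lognormal(5.0, 0.3, n)
        vox = vals.reshape((10, 10, 10))
        coords = np.argwhere(np.ones((10, 10, 10), dtype=bool))
        res = summarize([coords], make_volume(vox), self._stats(), 0.0, 0.0, 0.004)
        rel = (vals - 100.0) / 100.0
        assert res.s_rel_p75 == pytest.approx(percentile_oracle(rel, 75), rel=1e-10)
        assert res.s_rel_p90 == pytest.approx(percentile_oracle(rel, 90), rel=1e-10)

    def test_empty_lesion_set_flags_summaries_absent(self):
        res = summarize([], make_volume(np.zeros((2, 2, 2))), self._stats(),
                        141.5, 4.15, 0.004)
        assert res.volume_hyper_cm3 == 0.0
        assert res.n_objects == 0
        assert res.s_rel_mean is None and res.s_rel_p90 is None
        assert not res.test_positive


class TestPipelineInvariants:
    def _setup(self, rng):
        vox = rng.normal(100, 10, (24, 24, 8))
        vox[8:16, 8:16, 2:5] += 80.0
        image = make_volume(vox.clip(0))
        bone = RegionMask(np.ones((24, 24, 8), dtype=bool))
        roi = ReferenceROI(np.array(
            [[r, c, 7] for r in range(24) for c in range(10)]))
        return image, bone, roi

    def test_threshold_monotonicity_nests_voxel_sets(self, rng):
        image, bone, roi = self._setup(rng)
        prev = None
        prev_vol = np.inf
        for k in (1.0, 2.0, 2.64, 3.0, 4.15, 5.0):
            res = quantify_image_set(image, bone, roi, ThresholdSpec(k))
            vox_set = set()
            for les in res.lesions:
                vox_set |= set(map(tuple, les.coordinates))
            if prev is not None:
                assert vox_set <= prev
                assert res.volume_hyper_cm3 <= prev_vol
            prev, prev_vol = vox_set, res.volume_hyper_cm3

    def test_every_s_rel_exceeds_relative_threshold(self, rng):
        image, bone, roi = self._setup(rng)
        res = quantify_image_set(image, bone, roi, ThresholdSpec(4.15))
        rel_T = (res.threshold - res.roi_stats.mean) / res.roi_stats.mean
        for les in res.lesions:
            assert (les.s_rel_hyper > rel_T).all()

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(st.floats(0.1, 50.0))
    def test_intensity_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        image, bone, roi = self._setup(rng)
        scaled = make_volume(image.voxels * c, image.spacing)
        a = quantify_image_set(image, bone, roi, ThresholdSpec(4.15))
        b = quantify_image_set(scaled, bone, roi, ThresholdSpec(4.15))
        assert a.n_objects == b.n_objects
        assert a.volume_hyper_cm3 == pytest.approx(b.volume_hyper_cm3)
        if a.s_rel_mean is not None:
            assert a.s_rel_mean == pytest.approx(b.s_rel_mean, rel=1e-9)

    def test_volume_equals_voxel_count_times_voxel_volume(self, rng):
        image, bone, roi = self._setup(rng)
        res = quantify_image_set(image, bone, roi, ThresholdSpec(3.0))
        n = sum(les.size for les in res.lesions)
        assert res.volume_hyper_cm3 == pytest.approx(n * 0.004)

    def test_preset_k_values(self):
        assert PRESET_K == {"spine": 4.15, "si": 2.64}
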