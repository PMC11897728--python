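"""Permutation machinery: smoothing, null, thresholding, clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from emopac import permstats
from emopac.permstats import PermutationConfig


class TestSmoothMap:
    def test_constant_unchanged_including_edges(self):
        m = np.full((7, 9), 3.25)
        assert np.allclose(permstats.smooth_map(m), m)

    def test_single_impulse_center_value(self):
        m = np.zeros((11, 11))
        m[5, 5] = 1.0
        out = permstats.smooth_map(m, halfwidth=2)
        assert out[5, 5] == pytest.approx(1.0 / 25.0)
        assert out[5, 8] == 0.0

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.tile(np.arange(20.0), (9, 1))
        out = permstats.smooth_map(ramp, halfwidth=2)
        assert np.allclose(out[2:-2, 2:-2], ramp[2:-2, 2:-2], atol=1e-9)

    def test_negative_halfwidth_rejected(self):
        with pytest.raises(ValueError):
            permstats.smooth_map(np.zeros((5, 5)), halfwidth=-1)

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 3))
    def test_preserves_mean_of_symmetric_constant_rows(self, h):
        m = np.outer(np.ones(8), np.ones(10)) * 2.0
        assert np.allclose(permstats.smooth_map(m, h), 2.0)


class TestBuildNull:
    def test_identical_maps_give_zero_difference(self):
        maps = np.random.default_rng(0).standard_normal((3, 10, 12))
        obs = permstats.observed_difference(maps, maps.copy())
        assert np.allclose(obs, 0.0)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(1)
        act = rng.standard_normal((3, 8, 9))
        ref = rng.standard_normal((3, 8, 9))
        cfg = PermutationConfig(n_permutations=150, seed=5)
        a = permstats.build_null(act, ref, cfg)
        b = permstats.build_null(act, ref, cfg)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.sd, b.sd)

    def test_null_spread_shrinks_with_participants(self):
        rng = np.random.default_rng(2)
        sds = {}
        for n in (4, 16):
            act = rng.standard_normal((n, 12, 15))
            ref = rng.standard_normal((n, 12, 15))
            cfg = PermutationConfig(n_permutations=300, seed=3,
                                    smoothing_halfwidth=0)
            sds[n] = permstats.build_null(act, ref, cfg).sd.mean()
        # i.i.d. maps: element sd of the grand mean scales as 1/sqrt(n)
        assert sds[4] / sds[16] == pytest.approx(2.0, rel=0.25)

    def test_too_few_participants_rejected(self):
        one = np.zeros((1, 5, 5))
        with pytest.raises(ValueError):
            permstats.build_null(one, one, PermutationConfig(n_permutations=100))

    def test_mismatched_frequency_axes_rejected(self):
        with pytest.raises(ValueError):
            permstats.build_null(np.zeros((2, 5, 5)), np.zeros((2, 6, 5)),
                                 PermutationConfig(n_permutations=100))


class TestThreshold:
    def unit_null(self, shape):
        return permstats.NullDistribution(mean=np.zeros(shape),
                                          sd=np.ones(shape),
                                          n_permutations=2000)

    def test_observed_at_null_mean_is_not_significant(self):
        p, z, mask = permstats.threshold_normal(np.zeros((4, 4)),
                                                self.unit_null((4, 4)), 0.001)
        assert np.allclose(p, 1.0)
        assert not mask.any()

    def test_normal_quantile_boundary(self):
        # z = 3.2905 sits exactly at the two-sided p = 0.001 boundary and
        # the strict '<' excludes it; anything just above crosses
        assert 2 * norm.sf(3.2905) == pytest.approx(0.001, rel=1e-4)
        obs = np.array([[3.2905, 3.30]])
        p, z, mask = permstats.threshold_normal(obs, self.unit_null((1, 2)), 0.001)
        assert not mask[0, 0]
        assert mask[0, 1]

    def test_strong_effect_flagged_positive(self):
        null = permstats.NullDistribution(mean=np.zeros((3, 3)),
                                          sd=np.full((3, 3), 0.1),
                                          n_permutations=2000)
        obs = np.zeros((3, 3))
        obs[1, 1] = 2.0
        p, z, mask = permstats.threshold_normal(obs, null, 0.001)
        assert mask[1, 1] and z[1, 1] > 0
        assert mask.sum() == 1

    def test_zero_variance_elements_excluded(self):
        null = self.unit_null((2, 2))
        null.sd = np.array([[1.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="zero permutation variance"):
            p, z, mask = permstats.threshold_normal(np.full((2, 2), 9.0), null)
        assert not mask[0, 1] and p[0, 1] == 1.0
        assert mask[0, 0]


class TestClusterFilter:
    def blob_mask(self, size, shape=(30, 30)):
        mask = np.zeros(shape, dtype=bool)
        filled = 0
        for i in range(shape[0]):
            for j in range(shape[1]):
                if filled < size:
                    mask[i, j] = True
                    filled += 1
        return mask

    def test_blob_of_99_removed_at_k100(self):
        mask = self.blob_mask(99)
        out = permstats.cluster_filter(mask, np.ones_like(mask, dtype=np.int8),
                                       cluster_k=100)
        assert not out.any()

    def test_blob_of_exactly_100_retained(self):
        mask = self.blob_mask(100)
        out = permstats.cluster_filter(mask, np.ones_like(mask, dtype=np.int8),
                                       cluster_k=100)
        assert out.sum() == 100

    def test_only_large_blob_survives(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[:10, :15] = True  # 150
        mask[30:35, 30:40] = True  # 50
        out = permstats.cluster_filter(mask, np.ones_like(mask, dtype=np.int8),
                                       cluster_k=100)
        assert out.sum() == 150
        assert not out[30:, 30:].any()

    def test_opposite_signs_split_components(self):
        mask = np.zeros((5, 8), dtype=bool)
        mask[2, 1:7] = True
        direction = np.ones((5, 8), dtype=np.int8)
        direction[2, 4:] = -1  # 3 positive + 3 negative adjacent
        out = permstats.cluster_filter(mask, direction, cluster_k=4)
        assert not out.any()
        out2 = permstats.cluster_filter(mask, direction, cluster_k=3)
        assert out2.sum() == 6

    def test_eight_connectivity_bridges_diagonals(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[np.arange(5), np.arange(5)] = True  # diagonal line
        direction = np.ones((6, 6), dtype=np.int8)
        assert not permstats.cluster_filter(mask, direction, 5, connectivity=4).any()
        assert permstats.cluster_filter(mask, direction, 5, connectivity=8).sum() == 5

    @settings(max_examples=20, derandomize=True)
    @given(st.integers(0, 2 ** 16 - 1), st.integers(1, 30))
    def test_filtering_only_shrinks_masks(self, seed, k):
        rng = np.random.default_rng(seed)
        mask = rng.random((12, 12)) < 0.3
        direction = np.where(rng.random((12, 12)) < 0.5, 1, -1).astype(np.int8)
        out = permstats.cluster_filter(mask, direction, cluster_k=k)
        assert not (out & ~mask).any()


class TestFullProcedure:
    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(4)
        act = rng.standard_normal((4, 10, 12))
        ref = rng.standard_normal((4, 10, 12))
        cfg = PermutationConfig(n_permutations=200, seed=9)
        a = permstats.run_permutation_test(act, ref, cfg)
        b = permstats.run_permutation_test(act + 11.0, ref + 11.0, cfg)
        assert np.allclose(a.z_values, b.z_values, atol=1e-8)
        assert np.array_equal(a.mask, b.mask)

    def test_injected_blob_detected_with_direction(self):
        rng = np.random.default_rng(5)
        act = rng.standard_normal((6, 20, 24)) * 0.3
        ref = rng.standard_normal((6, 20, 24)) * 0.3
        act[:, 5:12, 8:18] += 4.0
        cfg = PermutationConfig(n_permutations=400, cluster_k=30, seed=2)
        result = permstats.run_permutation_test(act, ref, cfg)
        assert result.mask[8, 12]
        assert result.direction[8, 12] == 1
        assert not result.mask[0:3, 0:3].any()

    def test_empirical_mode_agrees_on_strong_effect(self):
        rng = np.random.default_rng(6)
        act = rng.standard_normal((5, 12, 12)) * 0.2
        ref = rng.standard_normal((5, 12, 12)) * 0.2
        act[:, 3:9, 3:9] += 3.0
        cfg = PermutationConfig(n_permutations=400, cluster_k=10, seed=8,
                                alpha=0.01, use_empirical=True)
        result = permstats.run_permutation_test(act, ref, cfg)
        assert result.mask[5, 5]
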