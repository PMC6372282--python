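"""Coupling maps, fingerprints, cosine similarity and permutation inference."""

from itertools import combinations

import numpy as np
import pytest

from sonoprint import connectivity as conn
from sonoprint import synthetic as syn


GRID = (20, 20, 12)
SPACING = 1.0


def _flat(ts):
    return ts.reshape(-1, ts.shape[-1]).T  # (t, v)


class TestMakeRoi:
    def test_midline_mirror_shares_column(self):
        centre = ((GRID[0] - 1) / 2 * SPACING, 10.0, 6.0)
        roi = conn.make_roi(centre, GRID, SPACING, radius_mm=4.0)
        assert {tuple(v) for v in roi.left} == {tuple(v) for v in roi.right}

    def test_tiny_radius_single_voxel(self):
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=0.4)
        assert len(roi.right) == 1 and len(roi.left) == 1

    def test_sphere_volume(self):
        grid = (80, 40, 40)
        roi = conn.make_roi((30.0, 10.0, 10.0), grid, 0.5, radius_mm=4.0)
        expected = 4.0 / 3.0 * np.pi * 4.0 ** 3 / 0.5 ** 3
        assert abs(len(roi.right) - expected) / expected < 0.2

    def test_centre_outside_grid(self):
        with pytest.raises(ValueError):
            conn.make_roi((100.0, 0.0, 0.0), GRID, SPACING)


class TestSeedMap:
    def _data(self, seed=0, n_t=300):
        rng = np.random.default_rng(seed)
        return rng.standard_normal((*GRID, n_t))

    def test_seed_voxel_own_value_hits_clip_bound(self):
        # midline single-voxel ROI on an odd-width grid: left and right members
        # coincide, so the seed voxel's own map value is the clipped
        # self-correlation, z = 2
        grid = (21, 20, 12)
        X = np.random.default_rng(0).standard_normal((*grid, 300))
        roi = conn.make_roi((10.0, 10.0, 6.0), grid, 1.0, radius_mm=0.4)
        assert np.array_equal(roi.left, roi.right)
        smap = conn.seed_map(X, roi, grid)
        iv = np.ravel_multi_index(roi.right[0], grid)
        assert smap[iv] == pytest.approx(2.0)

    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(1)
        n_t = 20_000
        base = rng.standard_normal(n_t)
        X = rng.standard_normal((*GRID, n_t))
        # plant r = 0.5 between the seed voxel pair and one target voxel
        target = (2, 3, 4)
        mix = base / np.sqrt(3.0)
        X[target] = mix + rng.standard_normal(n_t) * np.sqrt(1 - 1 / 3)
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=0.4)
        for v in (roi.right[0], roi.left[0]):
            X[tuple(v)] = mix + rng.standard_normal(n_t) * np.sqrt(1 - 1 / 3)
        smap = conn.seed_map(X, roi, GRID)
        iv = np.ravel_multi_index(np.asarray(target), GRID)
        # population r = 1/3 per hemisphere -> z = atanh(1/3)
        assert smap[iv] == pytest.approx(np.arctanh(1.0 / 3.0), abs=0.03)

    def test_sign_flip_antisymmetry(self):
        X = self._data(2)
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=0.4)
        target = (5, 5, 5)
        smap1 = conn.seed_map(X, roi, GRID)
        X2 = X.copy()
        X2[target] *= -1.0
        smap2 = conn.seed_map(X2, roi, GRID)
        iv = np.ravel_multi_index(np.asarray(target), GRID)
        assert smap2[iv] == pytest.approx(-smap1[iv], abs=1e-12)

    def test_affine_invariance(self):
        X = self._data(3)
        rng = np.random.default_rng(4)
        scale = rng.uniform(0.5, 2.0, GRID)[..., None]
        shift = rng.normal(0.0, 5.0, GRID)[..., None]
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=2.0)
        np.testing.assert_allclose(conn.seed_map(X * scale + shift, roi, GRID),
                                   conn.seed_map(X, roi, GRID), atol=1e-10)


class TestFingerprint:
    def test_within_network_above_distal(self, tiny_bold_pair, rois_and_targets):
        control, _ = tiny_bold_pair
        rois, targets = rois_and_targets
        X = control.timeseries[(0, 0)]
        vals, names = conn.fingerprint(X, rois["SMA"], targets,
                                       control.grid_shape)
        _, partition = syn.default_roi_layout(control.grid_shape)
        within = [v for v, n in zip(vals, names) if partition[n] == "motor"]
        distal = [v for v, n in zip(vals, names) if partition[n] != "motor"]
        assert min(within) > max(distal)

    def test_independent_data_near_zero(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((*GRID, 400))
        seed = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=1.0)
        t1 = conn.make_roi((15.0, 16.0, 6.0), GRID, SPACING, radius_mm=1.0)
        vals, _ = conn.fingerprint(X, seed, [t1], GRID)
        assert abs(vals[0]) < 3.0 / np.sqrt(400)

    def test_overlap_rejected(self):
        X = np.random.default_rng(6).standard_normal((*GRID, 120))
        seed = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=2.0)
        with pytest.raises(ValueError, match="overlap"):
            conn.fingerprint(X, seed, [seed], GRID)


class TestSelfCoupling:
    def test_shared_series_hits_bound(self):
        X = np.zeros((*GRID, 50))
        t = np.sin(np.linspace(0, 20, 50))
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=1.2)
        for v in np.vstack([roi.left, roi.right]):
            X[tuple(v)] = t
        assert conn.self_coupling(X, roi, GRID) == pytest.approx(2.0)

    def test_independent_voxels_near_zero(self):
        X = np.random.default_rng(7).standard_normal((*GRID, 500))
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=2.0)
        assert abs(conn.self_coupling(X, roi, GRID)) < 0.05

    def test_monotone_in_shared_fraction(self):
        rng = np.random.default_rng(8)
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=2.0)
        shared = rng.standard_normal(300)
        vals = []
        for a in (0.0, 0.5, 1.0, 2.0):
            X = rng.standard_normal((*GRID, 300))
            for v in np.vstack([roi.left, roi.right]):
                X[tuple(v)] += a * shared
            vals.append(conn.self_coupling(X, roi, GRID))
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_single_voxel_roi_rejected(self):
        X = np.random.default_rng(9).standard_normal((*GRID, 100))
        roi = conn.make_roi((15.0, 10.0, 6.0), GRID, SPACING, radius_mm=0.4)
        roi.left = roi.left[:0]  # degenerate: one total voxel
        roi.right = roi.right[:1]
        with pytest.raises(ValueError):
            conn.self_coupling(X, roi, GRID)


class TestPercentileMap:
    def test_uniform_correlation(self):
        rng = np.random.default_rng(10)
        n_v, n_t, r0 = 120, 4000, 0.5
        shared = rng.standard_normal(n_t)
        X = (np.sqrt(r0) * shared[None, :]
             + np.sqrt(1 - r0) * rng.standard_normal((n_v, n_t)))
        pmap = conn.percentile_coupling_map(X.T, q=98.0)
        assert np.abs(pmap - np.arctanh(r0)).max() < 0.1

    def test_global_component_raises_map(self):
        rng = np.random.default_rng(11)
        n_v, n_t = 150, 600
        base = rng.standard_normal((n_v, n_t))
        g = rng.standard_normal(n_t)
        low = conn.percentile_coupling_map(base.T, q=98.0)
        high = conn.percentile_coupling_map((base + 1.0 * g[None, :]).T, q=98.0)
        assert np.all(high > low)

    def test_q100_respects_bound(self):
        X = np.random.default_rng(12).standard_normal((40, 100))
        assert conn.percentile_coupling_map(X.T, q=100.0).max() <= 2.0


class TestGroupReduce:
    def test_full_rank_reduction_is_lossless(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((60, 40))  # (t, v)
        red = conn.group_reduce([X], k=60)
        Xc = X - X.mean(axis=0)
        corr_full = np.corrcoef(Xc.T)
        S = red.data / np.linalg.norm(red.data, axis=0)
        np.testing.assert_allclose(S.T @ S, corr_full, atol=1e-8)

    def test_low_rank_data_exact_at_small_k(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((300, 10)) @ rng.standard_normal((10, 80))
        red = conn.group_reduce([X], k=200)  # k above the true rank
        Xc = X - X.mean(axis=0)
        np.testing.assert_allclose(
            (red.data / np.linalg.norm(red.data, axis=0)).T
            @ (red.data / np.linalg.norm(red.data, axis=0)),
            np.corrcoef(Xc.T), atol=1e-7)

    def test_reduced_fingerprints_close_to_full(self, tiny_bold_pair,
                                                rois_and_targets):
        control, _ = tiny_bold_pair
        rois, targets = rois_and_targets
        X = control.timeseries[(0, 0)]
        grid = control.grid_shape
        full_vals, _ = conn.fingerprint(X, rois["SMA"], targets, grid)
        red = conn.group_reduce([X], k=150)
        red_vals, _ = conn.fingerprint(red, rois["SMA"], targets, grid)
        assert np.abs(full_vals - red_vals).max() < 0.05


class TestCosine:
    def test_identity_and_scale_invariance(self):
        f = np.array([0.3, 0.1, 0.6])
        assert conn.cosine_similarity(f, f) == pytest.approx(1.0)
        assert conn.cosine_similarity(f, 3.0 * f) == pytest.approx(1.0)

    def test_closed_form(self):
        assert conn.cosine_similarity(np.array([1.0, 1.0]),
                                      np.array([1.0, 0.0])) == pytest.approx(
            1.0 / np.sqrt(2.0))

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            conn.cosine_similarity(np.zeros(3), np.ones(3))


class TestPermutation:
    @pytest.mark.parametrize("n, g, expected", [(18, 9, 24309), (2, 1, 0), (6, 3, 9)])
    def test_count_exhaustive(self, n, g, expected):
        assert conn.count_exhaustive(n, g) == expected

    def test_count_requires_balance(self):
        with pytest.raises(ValueError):
            conn.count_exhaustive(5, 2)

    def test_exhaustive_enumeration_size(self):
        rng = np.random.default_rng(15)
        F = rng.standard_normal((18, 7)) + 1.0
        labels = ["control"] * 9 + ["stim"] * 9
        res = conn.permutation_test(F, labels, mode="exhaustive")
        assert res.exhaustive
        assert res.n_permutations == 24309

    def test_identical_fingerprints_high_p(self):
        F = np.tile(np.array([0.5, 0.2, 0.8, 0.1]), (8, 1))
        labels = ["a"] * 4 + ["b"] * 4
        res = conn.permutation_test(F, labels, mode="exhaustive")
        assert res.p_value > 0.99

    def test_two_vs_two_hand_enumeration(self):
        """C(4,2)/2 - 1 = 2 relabellings; null values verified by hand."""
        F = np.array([[1.0, 0.0], [0.9, 0.1], [0.0, 1.0], [0.1, 0.9]])
        labels = ["a", "a", "b", "b"]
        res = conn.permutation_test(F, labels, mode="exhaustive")
        assert res.n_permutations == 2
        # hand enumeration: swap one member across groups, two distinct ways
        hand = []
        for swap in ((1, 2), (1, 3)):
            g1 = [0, swap[1]]
            g2 = [i for i in range(4) if i not in g1]
            hand.append(conn.cosine_similarity(F[g1].mean(axis=0),
                                               F[g2].mean(axis=0)))
        np.testing.assert_allclose(np.sort(res.null_distribution),
                                   np.sort(hand), atol=1e-12)

    def test_monte_carlo_agrees_with_exhaustive(self):
        rng = np.random.default_rng(16)
        F = rng.standard_normal((12, 5)) + 0.8
        labels = ["a"] * 6 + ["b"] * 6
        ex = conn.permutation_test(F, labels, mode="exhaustive")
        mc = conn.permutation_test(F, labels, mode="monte_carlo", n_mc=20000,
                                   seed=0)
        assert mc.p_value == pytest.approx(ex.p_value, abs=0.02)

    def test_unbalanced_falls_back(self):
        rng = np.random.default_rng(17)
        F = rng.standard_normal((7, 4)) + 1.0
        labels = ["a"] * 3 + ["b"] * 4
        with pytest.warns(UserWarning, match="unbalanced"):
            res = conn.permutation_test(F, labels, mode="exhaustive", seed=1)
        assert not res.exhaustive

    def test_bounds(self, tiny_bold_pair, rois_and_targets):
        control, stim = tiny_bold_pair
        rois, targets = rois_and_targets
        grid = control.grid_shape
        for ds in (control, stim):
            vals, _ = conn.fingerprint(ds.timeseries[(0, 0)], rois["SMA"],
                                       targets, grid)
            assert np.all(np.abs(vals) <= 2.0)
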