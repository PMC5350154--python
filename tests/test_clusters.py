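from itertools import product

import numpy as np
import pytest
from scipy import stats

from betachoice.clusters import (
    CELL_ORDER,
    Adjacency,
    ContrastSpec,
    apply_contrast,
    cluster_permutation,
    condition_means,
    conjunction,
    group_t_map,
    independent_t_map,
    two_sample_cluster_permutation,
)


def small_adjacency(n_ch: int = 4) -> Adjacency:
    """Chain-graph channel adjacency for compact synthetic grids."""
    a = np.zeros((n_ch, n_ch), bool)
    for i in range(n_ch - 1):
        a[i, i + 1] = a[i + 1, i] = True
    return Adjacency(tuple(f"ch{i}" for i in range(n_ch)), a)


def _null_images(rng, n_subj=10, shape=(4, 8, 10)):
    return rng.standard_normal((n_subj, *shape))


class TestConditionMeans:
    def test_identical_maps_give_identical_cell_means(self):
        m = np.arange(12.0).reshape(1, 3, 4)
        vals = np.repeat(m, 8, axis=0)[:, None]  # 8 trials, 1 channel
        sign = np.array(["positive", "negative"] * 4)
        correct = np.array([True, True, False, False] * 2)
        means, counts = condition_means(vals, sign, correct)
        for cell in CELL_ORDER:
            assert np.allclose(means[cell], m)
            assert counts[cell] == 2

    def test_cell_means_match_a_naive_loop(self, rng):
        vals = rng.random((40, 2, 5, 6))
        sign = rng.choice(["positive", "negative"], 40)
        correct = rng.choice([True, False], 40)
        means, _ = condition_means(vals, sign, correct)
        for (s, c) in CELL_ORDER:
            picks = [vals[i] for i in range(40) if sign[i] == s and correct[i] == c]
            assert np.allclose(means[(s, c)], np.mean(picks, axis=0))

    def test_missing_required_cell_is_an_explicit_error(self, rng):
        vals = rng.random((10, 1, 2, 2))
        sign = np.array(["positive"] * 10)  # no negative trials at all
        correct = rng.choice([True, False], 10)
        with pytest.raises(ValueError):
            condition_means(vals, sign, correct)

    def test_missing_cell_flagged_when_not_required(self, rng):
        vals = rng.random((10, 1, 2, 2))
        sign = np.array(["positive"] * 5 + ["negative"] * 5)
        correct = np.ones(10, bool)
        means, counts = condition_means(
            vals, sign, correct, require=(("positive", True), ("negative", True))
        )
        assert means[("positive", False)] is None
        assert counts[("negative", False)] == 0
        with pytest.raises(ValueError):
            apply_contrast(means, ContrastSpec.preset("interaction"))


class TestApplyContrast:
    def test_equal_means_give_zero_image(self):
        m = {cell: np.ones((2, 3, 4)) for cell in CELL_ORDER}
        out = apply_contrast(m, ContrastSpec.preset("interaction"))
        assert np.allclose(out, 0.0)

    def test_printed_interaction_vector(self, rng):
        a, b, c, d = (rng.random((1, 2, 2)) for _ in range(4))
        means = dict(zip(CELL_ORDER, [a, b, c, d]))
        out = apply_contrast(means, ContrastSpec.preset("interaction"))
        assert np.allclose(out, -a + b + c - d)

    def test_interaction_equals_difference_of_differences(self, rng):
        means = dict(zip(CELL_ORDER, (rng.random((2, 3, 3)) for _ in range(4))))
        out = apply_contrast(means, ContrastSpec.preset("interaction"))
        # chose ">" minus chose "<" within correct plus within incorrect
        dd = (means[CELL_ORDER[1]] - means[CELL_ORDER[0]]) + (
            means[CELL_ORDER[2]] - means[CELL_ORDER[3]]
        )
        assert np.allclose(out, dd)

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            ContrastSpec((1.0, -1.0, np.inf, 0.0))


class TestGroupTMap:
    def test_all_zero_images_give_zero_t(self):
        t = group_t_map(np.zeros((5, 2, 3, 4)))
        assert np.all(t == 0.0)

    def test_matches_textbook_formula_on_one_bin(self, rng):
        x = 2.0 + rng.standard_normal((12, 1, 1, 1))
        t = group_t_map(x)[0, 0, 0]
        v = x[:, 0, 0, 0]
        expected = v.mean() / (v.std(ddof=1) / np.sqrt(12))
        assert t == pytest.approx(expected, rel=1e-12)
        # and scipy agrees
        assert t == pytest.approx(stats.ttest_1samp(v, 0.0).statistic, rel=1e-12)

    def test_sign_flip_antisymmetry(self, rng):
        x = rng.standard_normal((8, 2, 3, 4))
        assert np.allclose(group_t_map(-x), -group_t_map(x), equal_nan=True)


class TestClusterPermutation:
    def test_all_zero_contrasts_give_empty_result(self):
        res = cluster_permutation(np.zeros((6, 4, 8, 10)), small_adjacency(), n_perm=20, seed=0)
        assert res.clusters == []

    def test_fixed_seed_reproduces_exactly(self, rng):
        x = _null_images(rng)
        a = cluster_permutation(x, small_adjacency(), n_perm=50, seed=3)
        b = cluster_permutation(x, small_adjacency(), n_perm=50, seed=3)
        assert np.array_equal(a.null_max_mass, b.null_max_mass)
        assert [c.p for c in a.clusters] == [c.p for c in b.clusters]

    def test_subject_order_does_not_change_pvalues(self, rng):
        # relabeling subjects leaves the null distribution unchanged, so
        # p-values agree up to Monte-Carlo error
        x = _null_images(rng, n_subj=8)
        x[:, 1:3, 2:5, 3:7] += 2.0
        a = cluster_permutation(x, small_adjacency(), threshold_p=0.05, n_perm=500, seed=5)
        b = cluster_permutation(x[::-1], small_adjacency(), threshold_p=0.05, n_perm=500, seed=5)
        assert np.allclose(a.t_map, b.t_map, equal_nan=True)
        for ca, cb in zip(a.clusters, b.clusters):
            se = np.sqrt(max(ca.p * (1 - ca.p), 1e-4) / a.n_permutations)
            assert cb.p == pytest.approx(ca.p, abs=4 * se + 2 / a.n_permutations)

    def test_global_sign_flip_swaps_cluster_families(self, rng):
        x = _null_images(rng, n_subj=10)
        x[:, 0:2, 1:4, 1:5] += 1.5
        a = cluster_permutation(x, small_adjacency(), threshold_p=0.01, n_perm=100, seed=7)
        b = cluster_permutation(-x, small_adjacency(), threshold_p=0.01, n_perm=100, seed=7)
        assert np.allclose(a.t_map, -b.t_map, equal_nan=True)
        pos_a = sorted(c.mass for c in a.clusters if c.sign > 0)
        neg_b = sorted(-c.mass for c in b.clusters if c.sign < 0)
        assert np.allclose(pos_a, neg_b)

    def test_injected_effect_yields_overlapping_significant_cluster(self, rng):
        x = _null_images(rng, n_subj=22, shape=(4, 12, 15))
        block = np.zeros((4, 12, 15), bool)
        block[1:3, 4:9, 5:11] = True
        x[:, block] += 1.6
        res = cluster_permutation(x, small_adjacency(), n_perm=200, seed=1)
        sig = res.significant()
        assert sig
        top = sig[0]
        hits = block[tuple(top.bins.T)].sum()
        assert hits / block.sum() >= 0.5
        assert top.sign > 0 and top.p < 0.05

    def test_monte_carlo_p_matches_exhaustive_enumeration(self, rng):
        # 2^8 = 256 sign patterns: enumeration is the oracle for the MC p-value
        n_subj = 8
        x = _null_images(rng, n_subj=n_subj, shape=(3, 6, 8))
        x[:, 0:2, 1:4, 2:5] += 1.2
        adj = small_adjacency(3)
        res = cluster_permutation(x, adj, threshold_p=0.05, n_perm=400, seed=9)
        assert res.clusters

        # exhaustive null of the max-|mass| statistic using the same machinery
        from betachoice.clusters import _cluster_masses, _sign_flip_t

        flips = np.array(list(product([-1.0, 1.0], repeat=n_subj)))
        xf = x.reshape(n_subj, -1)
        tmaps = _sign_flip_t(xf, flips)
        t_crit = res.t_crit
        neighbor_lists = [np.flatnonzero(r) for r in adj.channel_neighbors]
        exact_null = np.empty(len(flips))
        for i in range(len(flips)):
            supra = np.abs(tmaps[i]) > t_crit
            _, masses = _cluster_masses(supra, tmaps[i], x.shape[1:], neighbor_lists)
            exact_null[i] = max((abs(m) for m in masses), default=0.0)
        for c in res.clusters[:3]:
            p_exact = np.mean(exact_null >= abs(c.mass))
            se = np.sqrt(max(p_exact * (1 - p_exact), 1e-4) / res.n_permutations)
            assert c.p == pytest.approx(p_exact, abs=4 * se + 2 / res.n_permutations)

    def test_invalid_arguments_rejected(self, rng):
        x = _null_images(rng)
        with pytest.raises(ValueError):
            cluster_permutation(x, small_adjacency(), n_perm=0)
        with pytest.raises(ValueError):
            cluster_permutation(x, small_adjacency(), threshold_p=1.5)
        with pytest.raises(ValueError):
            cluster_permutation(x[:1], small_adjacency())
        with pytest.raises(ValueError):
            cluster_permutation(x, small_adjacency(5))

    def test_adjacency_validation(self):
        bad = np.zeros((2, 2), bool)
        bad[0, 1] = True  # asymmetric
        with pytest.raises(ValueError):
            Adjacency(("a", "b"), bad)
        with pytest.raises(ValueError):
            Adjacency(("a", "b"), np.eye(2, dtype=bool))


class TestConjunction:
    def test_minimum_t_map_bounds_both_inputs(self, rng):
        xc = _null_images(rng, n_subj=10)
        xi = _null_images(rng, n_subj=10)
        res = conjunction(xc, xi, small_adjacency(), channel_restriction=["ch0", "ch1"],
                          n_perm=50, seed=0)
        assert np.all(
            (res.min_t_map <= res.correct.t_map + 1e-12)
            | np.isnan(res.min_t_map)
        )
        assert np.all(
            (res.min_t_map <= res.incorrect.t_map + 1e-12)
            | np.isnan(res.min_t_map)
        )

    def test_effect_only_in_correct_trials_fails_the_conjunction(self, rng):
        shape = (4, 10, 12)
        xc = _null_images(rng, n_subj=16, shape=shape)
        xi = _null_images(rng, n_subj=16, shape=shape)
        xc[:, 0:2, 3:7, 4:9] += 2.0  # effect in the correct-trial contrast only
        res = conjunction(xc, xi, small_adjacency(), channel_restriction=["ch0", "ch1"],
                          threshold_p=0.01, n_perm=200, seed=2)
        assert res.correct.significant()
        assert not res.conjunction_positive

    def test_effect_in_both_classes_overlaps(self, rng):
        shape = (4, 10, 12)
        xc = _null_images(rng, n_subj=16, shape=shape)
        xi = _null_images(rng, n_subj=16, shape=shape)
        for x in (xc, xi):
            x[:, 0:2, 3:7, 4:9] += 2.0
        res = conjunction(xc, xi, small_adjacency(), channel_restriction=["ch0", "ch1"],
                          threshold_p=0.01, n_perm=200, seed=3)
        assert res.conjunction_positive
        block = np.zeros((2, 10, 12), bool)
        block[:, 3:7, 4:9] = True
        assert block[tuple(res.overlap_bins.T)].mean() > 0.5

    def test_empty_channel_restriction_rejected(self, rng):
        x = _null_images(rng)
        with pytest.raises(ValueError):
            conjunction(x, x, small_adjacency(), channel_restriction=[])


class TestTwoSample:
    def test_t_map_matches_scipy(self, rng):
        a = rng.standard_normal((6, 1, 2, 2))
        b = 0.5 + rng.standard_normal((8, 1, 2, 2))
        t = independent_t_map(a, b)
        ref = stats.ttest_ind(a, b, axis=0).statistic
        assert np.allclose(t, ref)

    def test_group_difference_detected_and_null_calibrated(self, rng):
        shape = (4, 8, 10)
        a = _null_images(rng, n_subj=10, shape=shape)
        b = _null_images(rng, n_subj=10, shape=shape)
        same = two_sample_cluster_permutation(a, b, small_adjacency(),
                                              threshold_p=0.01, n_perm=150, seed=4)
        assert not same.significant()
        b2 = b.copy()
        b2[:, 1:3, 2:6, 3:8] += 2.5
        diff = two_sample_cluster_permutation(a, b2, small_adjacency(),
                                              threshold_p=0.01, n_perm=150, seed=4)
        assert diff.significant()
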