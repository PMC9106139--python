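"""Cluster permutation test, exact Wilcoxon, and Spearman + FDR statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aperiodic_net import montage
from aperiodic_net.inference import (
    ChannelAdjacency,
    build_adjacency,
    cluster_permutation_test,
    spearman_fdr,
    wilcoxon_signed_rank,
)


def chain_adjacency(n):
    """1-D chain neighbourhood: i ~ i+1."""
    nb = np.zeros((n, n), dtype=bool)
    for i in range(n - 1):
        nb[i, i + 1] = nb[i + 1, i] = True
    return ChannelAdjacency(labels=[f"ch{i:02d}" for i in range(n)], neighbors=nb)


# ---------------------------------------------------------------------------
# adjacency


class TestBuildAdjacency:
    def test_two_channels_full_quantile(self):
        coords = np.array([[0, 0, 0], [1, 0, 0]], float)
        adj = build_adjacency(coords, ["a", "b"], distance_quantile=1.0)
        assert adj.neighbors[0, 1] and adj.neighbors[1, 0]

    def test_equilateral_triangle_full_quantile(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        adj = build_adjacency(coords, list("abc"), distance_quantile=1.0)
        assert adj.neighbors.sum() == 6

    def test_biosemi32_default_neighbor_count(self, biosemi):
        labels, coords = biosemi
        adj = build_adjacency(coords, labels)
        assert 3 <= adj.mean_neighbor_count <= 8

    def test_coincident_coordinates_error(self):
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="coincident"):
            build_adjacency(coords, list("abc"))

    def test_symmetric_and_irreflexive(self, biosemi):
        labels, coords = biosemi
        nb = build_adjacency(coords, labels).neighbors
        assert np.array_equal(nb, nb.T)
        assert not nb.diagonal().any()


# ---------------------------------------------------------------------------
# cluster permutation test


class TestClusterPermutation:
    def test_identical_conditions_give_no_clusters(self, rng):
        a = rng.normal(size=(10, 8))
        res = cluster_permutation_test(a, a.copy() + 0.0, chain_adjacency(8), 200, seed=0)
        # a - a is all-zero: every channel t = 0, nothing suprathreshold
        assert res.clusters == []

    def test_planted_shift_detected(self, rng):
        a = rng.normal(size=(15, 12))
        b = a + rng.normal(0, 1.0, size=(15, 12))
        b[:, 4:8] += 1.5  # planted connected block, b > a
        res = cluster_permutation_test(a, b, chain_adjacency(12), 500, seed=1)
        sig = res.significant_clusters
        assert sig and sig[0].sign == -1
        assert len(set(sig[0].indices) & {4, 5, 6, 7}) >= 3

    def test_sign_symmetry(self, rng):
        a = rng.normal(size=(8, 6))
        b = rng.normal(size=(8, 6))
        adj = chain_adjacency(6)
        r1 = cluster_permutation_test(a, b, adj, 300, seed=3)
        r2 = cluster_permutation_test(b, a, adj, 300, seed=3)
        assert len(r1.clusters) == len(r2.clusters)
        for c1 in r1.clusters:
            match = [c2 for c2 in r2.clusters if tuple(c2.indices) == tuple(c1.indices)]
            assert match and match[0].sign == -c1.sign
            assert match[0].p_value == c1.p_value
            assert match[0].mass == pytest.approx(-c1.mass)

    def test_shift_invariance(self, rng):
        a = rng.normal(size=(8, 6))
        b = rng.normal(size=(8, 6))
        adj = chain_adjacency(6)
        r1 = cluster_permutation_test(a, b, adj, 300, seed=4)
        r2 = cluster_permutation_test(a + 7.0, b + 7.0, adj, 300, seed=4)
        assert [c.p_value for c in r1.clusters] == [c.p_value for c in r2.clusters]

    def test_channel_relabeling_invariance(self, rng):
        a = rng.normal(size=(9, 8))
        b = a + rng.normal(0, 0.5, size=(9, 8))
        n = 8
        perm = np.random.default_rng(0).permutation(n)
        nb = chain_adjacency(n).neighbors
        adj_p = ChannelAdjacency(
            labels=[f"ch{i:02d}" for i in range(n)], neighbors=nb[np.ix_(perm, perm)]
        )
        r1 = cluster_permutation_test(a, b, chain_adjacency(n), 300, seed=5)
        r2 = cluster_permutation_test(a[:, perm], b[:, perm], adj_p, 300, seed=5)
        assert sorted(c.p_value for c in r1.clusters) == sorted(
            c.p_value for c in r2.clusters
        )

    def test_deterministic_given_seed(self, rng):
        a = rng.normal(size=(8, 6))
        b = rng.normal(size=(8, 6)) + 0.8
        adj = chain_adjacency(6)
        r1 = cluster_permutation_test(a, b, adj, 200, seed=11)
        r2 = cluster_permutation_test(a, b, adj, 200, seed=11)
        np.testing.assert_array_equal(r1.null_distribution, r2.null_distribution)

    def test_zero_variance_channel_warns(self):
        a = np.random.default_rng(1).normal(size=(6, 4))
        b = a.copy()
        b[:, 1:] += np.random.default_rng(2).normal(size=(6, 3))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            cluster_permutation_test(a, b, chain_adjacency(4), 200, seed=0)

    def test_too_few_subjects_errors(self):
        a = np.zeros((2, 4))
        with pytest.raises(ValueError):
            cluster_permutation_test(a, a, chain_adjacency(4), 100, seed=0)

    def test_few_permutations_warns(self, rng):
        a = rng.normal(size=(6, 4))
        b = rng.normal(size=(6, 4))
        with pytest.warns(RuntimeWarning, match="permutations"):
            cluster_permutation_test(a, b, chain_adjacency(4), 50, seed=0)

    def test_null_calibration_smoke(self):
        """Family-wise false-positive rate is near the nominal 5 % level."""
        adj = chain_adjacency(16)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            a = rng.normal(size=(12, 16))
            b = rng.normal(size=(12, 16))
            res = cluster_permutation_test(a, b, adj, 200, seed=rep)
            hits += bool(res.significant_clusters)
        assert hits / n_rep < 0.18  # loose 3-sigma binomial bound around 0.05


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


def wilcoxon_enumeration_oracle(diffs):
    """Two-tailed p by brute force over all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = d.size
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [ranks[np.array(signs, bool)].sum() for signs in itertools.product([0, 1], repeat=n)]
    )
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_antisymmetric_differences_give_p_one(self):
        assert wilcoxon_signed_rank([-3, -2, -1, 1, 2, 3]) == pytest.approx(1.0)

    def test_all_positive_n6(self):
        p = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert p == pytest.approx(2 / 64)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(size=n), 1)  # rounding induces ties and zeros
        if np.all(d == 0):
            d[0] = 0.5
        assert wilcoxon_signed_rank(d) == pytest.approx(wilcoxon_enumeration_oracle(d))

    def test_matches_scipy_without_ties(self, rng):
        d = rng.normal(size=20)
        p_scipy = stats.wilcoxon(d, mode="exact").pvalue
        assert wilcoxon_signed_rank(d) == pytest.approx(p_scipy)

    def test_large_n_normal_approximation_is_close(self, rng):
        d = rng.normal(0.3, 1, size=40)
        p = wilcoxon_signed_rank(d)
        p_scipy = stats.wilcoxon(d, correction=True, mode="approx").pvalue
        assert p == pytest.approx(p_scipy, rel=0.05)


# ---------------------------------------------------------------------------
# Spearman + FDR


def bh_stepup_oracle(pvals, q=0.05):
    """Benjamini-Hochberg step-up rejections, straight from the definition."""
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * q
    reject = np.zeros(m, bool)
    if below.any():
        k = np.flatnonzero(below).max()
        reject[order[: k + 1]] = True
    return reject


class TestSpearmanFDR:
    def test_perfect_monotone_gives_rho_one(self, rng):
        x = np.arange(8.0)[:, None] + np.zeros((8, 3))
        x[:, 1] = rng.normal(size=8)
        y = np.arange(8.0) * 2 + 5
        tab = spearman_fdr(x, y)
        assert tab.rho[0] == pytest.approx(1.0)
        assert tab.rho[2] == pytest.approx(1.0)

    def test_rho_matches_rank_pearson_oracle(self, rng):
        x = rng.normal(size=(10, 4))
        x[:, 2] = np.round(x[:, 2], 0)  # induce ties
        y = rng.normal(size=10)
        tab = spearman_fdr(x, y)
        ry = stats.rankdata(y)
        for c in range(4):
            rx = stats.rankdata(x[:, c])
            expect = np.corrcoef(rx, ry)[0, 1]
            assert tab.rho[c] == pytest.approx(expect, abs=1e-12)

    def test_bh_family_example(self):
        reject = bh_stepup_oracle([0.01, 0.02, 0.03, 0.5])
        np.testing.assert_array_equal(reject, [True, True, True, False])

    @given(st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4))
    @settings(max_examples=100, deadline=None)
    def test_fdr_matches_stepup_oracle(self, pvals):
        """Package BH decisions equal the step-up definition on 4-element families."""
        from statsmodels.stats.multitest import multipletests

        reject, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, bh_stepup_oracle(pvals))

    def test_constant_channel_excluded_with_warning(self, rng):
        x = rng.normal(size=(8, 3))
        x[:, 1] = 4.2
        y = rng.normal(size=8)
        with pytest.warns(RuntimeWarning, match="constant"):
            tab = spearman_fdr(x, y)
        assert np.isnan(tab.rho[1]) and not tab.significant[1]

    def test_too_few_subjects_errors(self):
        with pytest.raises(ValueError):
            spearman_fdr(np.zeros((4, 2)), np.zeros(4))
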