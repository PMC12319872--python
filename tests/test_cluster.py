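import numpy as np
import pytest
from scipy import stats

from mindprobe import (ClusterPermutationTest, SpectralMatrix,
                       electrode_adjacency, find_clusters,
                       grand_difference_matrix, paired_t_map,
                       task_rest_similarity)


@pytest.fixture(scope="module")
def adjacency(layout):
    return electrode_adjacency(layout)


class TestPairedTMap:
    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(0)
        up = rng.standard_normal((30, 32, 27))
        lo = rng.standard_normal((30, 32, 27))
        t = paired_t_map(up, lo)
        oracle = stats.ttest_rel(up, lo, axis=0).statistic
        np.testing.assert_allclose(t, oracle, atol=1e-12)
        assert t.shape == (32, 27)

    def test_identical_stacks_give_zero_map(self):
        x = np.random.default_rng(1).standard_normal((5, 32, 27))
        np.testing.assert_array_equal(paired_t_map(x, x.copy()), 0.0)

    def test_single_pair_rejected(self):
        x = np.zeros((1, 32, 27))
        with pytest.raises(ValueError):
            paired_t_map(x, x)


def brute_force_clusters(t_map, threshold, adjacency):
    """Independent oracle: BFS over the explicit neighbor graph."""
    n_el, n_f = t_map.shape
    el_adj = adjacency.electrode
    out = []
    for sign in (+1, -1):
        mask = sign * t_map >= threshold
        seen = np.zeros_like(mask)
        for e0 in range(n_el):
            for f0 in range(n_f):
                if not mask[e0, f0] or seen[e0, f0]:
                    continue
                comp, queue = set(), [(e0, f0)]
                seen[e0, f0] = True
                while queue:
                    e, f = queue.pop()
                    comp.add((e, f))
                    nbrs = [(e2, f) for e2 in np.flatnonzero(el_adj[e])]
                    nbrs += [(e, f2) for f2 in (f - 1, f + 1) if 0 <= f2 < n_f]
                    for e2, f2 in nbrs:
                        if mask[e2, f2] and not seen[e2, f2]:
                            seen[e2, f2] = True
                            queue.append((e2, f2))
                out.append((frozenset(comp),
                            float(sum(t_map[e, f] for e, f in comp)), sign))
    return out


class TestFindClusters:
    def test_single_suprathreshold_cell(self, adjacency):
        t = np.zeros((32, 27))
        t[5, 10] = 3.0
        clusters = find_clusters(t, 2.0, adjacency)
        assert len(clusters) == 1
        assert clusters[0].members == frozenset({(5, 10)})
        assert clusters[0].mass == 3.0 and clusters[0].sign == 1

    def test_non_neighboring_electrodes_split(self, layout, adjacency):
        t = np.zeros((32, 27))
        fp1, o2 = layout.index("Fp1"), layout.index("O2")
        t[fp1, 10] = t[o2, 10] = 3.0
        assert len(find_clusters(t, 2.0, adjacency)) == 2

    def test_matches_brute_force_on_random_maps(self, adjacency):
        rng = np.random.default_rng(2)
        for _ in range(10):
            t = rng.standard_normal((32, 27)) * 1.5
            mine = {(c.members, round(c.mass, 9), c.sign)
                    for c in find_clusters(t, 2.0, adjacency)}
            oracle = {(m, round(mass, 9), s)
                      for m, mass, s in brute_force_clusters(t, 2.0, adjacency)}
            assert mine == oracle

    def test_opposite_signs_never_merge(self, adjacency):
        t = np.zeros((32, 27))
        t[5, 10], t[5, 11] = 3.0, -3.0
        clusters = find_clusters(t, 2.0, adjacency)
        assert sorted(c.sign for c in clusters) == [-1, 1]


class TestPermutationTest:
    def test_exhaustive_small_n_p_granularity(self, adjacency):
        """With 3 pairs all 2^3 sign patterns are enumerated; the smallest
        attainable p is 1/8."""
        rng = np.random.default_rng(3)
        up = rng.standard_normal((3, 32, 27)) + 2.0
        lo = rng.standard_normal((3, 32, 27))
        res = ClusterPermutationTest(up, lo, adjacency).fit(1000, seed=0)
        assert res.exhaustive and res.n_permutations == 8
        ps = [c.p_value for c in res.clusters]
        assert all(abs(p * 8 - round(p * 8)) < 1e-9 for p in ps)
        assert min(ps) >= 1 / 8

    def test_label_swap_flips_cluster_signs_not_p(self, adjacency):
        rng = np.random.default_rng(4)
        up = rng.standard_normal((10, 32, 27))
        up[:, 10:14, 5:9] += 1.0
        lo = rng.standard_normal((10, 32, 27))
        a = ClusterPermutationTest(up, lo, adjacency).fit(300, seed=7)
        b = ClusterPermutationTest(lo, up, adjacency).fit(300, seed=7)
        np.testing.assert_allclose(a.t_map, -b.t_map, atol=1e-12)
        key = lambda r: sorted((c.members, round(c.p_value, 12))
                               for c in r.clusters)
        assert key(a) == key(b)

    def test_matches_mne_cluster_finding(self, adjacency):
        """Cross-check observed clusters against MNE's implementation of
        the same test."""
        mne_stats = pytest.importorskip("mne.stats")
        from scipy import sparse

        rng = np.random.default_rng(5)
        up = rng.standard_normal((12, 32, 27))
        up[:, 5:9, 6:10] += 1.2
        lo = rng.standard_normal((12, 32, 27))
        res = ClusterPermutationTest(up, lo, adjacency).fit(200, seed=1)

        comb = mne_stats.combine_adjacency(
            sparse.csr_matrix(adjacency.electrode), 27)
        t_obs, clusters, _, _ = mne_stats.permutation_cluster_1samp_test(
            (up - lo).reshape(12, -1), threshold=res.threshold_t,
            n_permutations=100, adjacency=comb, tail=0, out_type="mask",
            seed=0, verbose="error")
        np.testing.assert_allclose(t_obs.reshape(32, 27), res.t_map,
                                   atol=1e-10)
        mne_sets = {frozenset(map(tuple, np.argwhere(m.reshape(32, 27))))
                    for m in clusters}
        my_sets = {c.members for c in res.clusters}
        assert my_sets == mne_sets

    def test_planted_block_detected(self, adjacency):
        rng = np.random.default_rng(6)
        up = rng.standard_normal((20, 32, 27))
        up[:, 8:16, 4:8] += 1.0
        lo = rng.standard_normal((20, 32, 27))
        res = ClusterPermutationTest(up, lo, adjacency).fit(500, seed=2)
        sig = res.significant(0.05)
        assert sig and sig[0].sign == 1

    def test_too_few_permutations_rejected(self, adjacency):
        x = np.zeros((5, 32, 27))
        with pytest.raises(ValueError):
            ClusterPermutationTest(x, x, adjacency).fit(50)


class TestGrandDifferenceAndSimilarity:
    def test_single_pair_gives_its_difference(self):
        rng = np.random.default_rng(7)
        a, b = (SpectralMatrix(rng.standard_normal((32, 27)))
                for _ in range(2))
        out = grand_difference_matrix([(a, b)])
        np.testing.assert_allclose(out.periodic, a.periodic - b.periodic)

    def test_antisymmetric_pairs_cancel(self):
        rng = np.random.default_rng(8)
        a = SpectralMatrix(rng.standard_normal((32, 27)))
        b = SpectralMatrix(rng.standard_normal((32, 27)))
        out = grand_difference_matrix([(a, b), (b, a)])
        np.testing.assert_allclose(out.periodic, 0.0, atol=1e-15)

    def test_similarity_identity_and_negation(self):
        m = SpectralMatrix(np.random.default_rng(9).standard_normal((32, 27)))
        neg = SpectralMatrix(-m.periodic)
        assert task_rest_similarity(m, m).r == pytest.approx(1.0)
        assert task_rest_similarity(m, neg).r == pytest.approx(-1.0)

    def test_independent_matrices_weakly_correlated(self):
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(40):
            a = SpectralMatrix(rng.standard_normal((32, 27)))
            b = SpectralMatrix(rng.standard_normal((32, 27)))
            hits += abs(task_rest_similarity(a, b).r) < 0.1
        assert hits >= 38

    def test_zero_variance_matrix_rejected(self):
        m = SpectralMatrix(np.zeros((32, 27)))
        with pytest.raises(ValueError):
            task_rest_similarity(m, m)
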