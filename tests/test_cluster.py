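"""MST single-linkage clustering and cluster refinement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgdecomp.cluster import (
    UNASSIGNED,
    compute_templates,
    default_n_clusters,
    minimum_spanning_tree,
    mst_cluster,
    refine,
)


def _dist_from_points(pts):
    pts = np.asarray(pts, float)
    d = np.abs(pts[:, None] - pts[None, :])
    return d


def _single_linkage_oracle(dist, n_clusters):
    """Brute-force agglomerative single linkage (independent of the MST path)."""
    n = dist.shape[0]
    clusters = [{i} for i in range(n)]
    while len(clusters) > n_clusters:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                w = min(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or w < best[0]:
                    best = (w, a, b)
        _, a, b = best
        clusters[a] |= clusters[b]
        del clusters[b]
    labels = np.empty(n, int)
    for lab, members in enumerate(clusters):
        for i in members:
            labels[i] = lab
    return labels


def _canon(labels):
    remap = {}
    return tuple(remap.setdefault(l, len(remap)) for l in labels)


class TestMstCluster:
    def test_three_point_example(self):
        d = np.array([[0, 0.1, 5], [0.1, 0, 5], [5, 5, 0]], float)
        labels = mst_cluster(d, 2)
        assert labels[0] == labels[1] != labels[2]

    def test_single_cluster(self, rng):
        d = _dist_from_points(rng.normal(size=7))
        assert len(set(mst_cluster(d, 1))) == 1

    def test_n_clusters_bounds(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError):
            mst_cluster(d, 0)
        with pytest.raises(ValueError):
            mst_cluster(d, 4)

    def test_tree_has_n_minus_one_edges(self, rng):
        d = _dist_from_points(rng.normal(size=9))
        assert len(minimum_spanning_tree(d)) == 8

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=3, max_size=10),
        st.integers(1, 4),
        st.integers(0, 2**31 - 1),
    )
    def test_equivalent_to_single_linkage_oracle(self, pts, n_clusters, _seed):
        n_clusters = min(n_clusters, len(pts))
        d = _dist_from_points(pts)
        heights = d[np.triu_indices(len(pts), 1)]
        if len(set(heights)) != len(heights):
            # tied merge heights admit several valid single-linkage
            # partitions; equality is only required on generic instances
            return
        ours = _canon(mst_cluster(d, n_clusters))
        oracle = _canon(_single_linkage_oracle(d, n_clusters))
        assert ours == oracle

    def test_order_independence(self, rng):
        pts = rng.normal(size=12)
        d = _dist_from_points(pts)
        labels = mst_cluster(d, 3)
        perm = rng.permutation(12)
        labels_p = mst_cluster(d[np.ix_(perm, perm)], 3)
        # same partition after undoing the permutation
        groups = {}
        for i, l in enumerate(labels_p):
            groups.setdefault(l, set()).add(int(perm[i]))
        orig = {}
        for i, l in enumerate(labels):
            orig.setdefault(l, set()).add(i)
        assert set(map(frozenset, groups.values())) == set(map(frozenset, orig.values()))


class TestRefine:
    def test_small_cluster_dissolved(self):
        d = _dist_from_points([0.0, 0.1, 10.0, 10.1, 10.2])
        labels = mst_cluster(d, 2)
        refined, pool = refine(labels, d, min_size=3)
        assert sorted(pool) == [0, 1]
        assert all(refined[i] == UNASSIGNED for i in pool)
        assert len({refined[i] for i in (2, 3, 4)}) == 1

    def test_merged_groups_split_on_internal_gap(self):
        # two tight 5-member groups, one label: internal MST gap edge 10x
        pts = [0.0, 0.1, 0.2, 0.3, 0.4, 50.0, 50.1, 50.2, 50.3, 50.4]
        d = _dist_from_points(pts)
        labels = np.zeros(10, int)
        refined, pool = refine(labels, d, min_size=3)
        assert not pool
        assert len(set(refined[:5])) == 1
        assert len(set(refined[5:])) == 1
        assert refined[0] != refined[5]

    def test_tight_cluster_unchanged(self):
        pts = [0.0, 0.9, 2.1, 3.0, 3.9, 5.1]
        d = _dist_from_points(pts)
        refined, pool = refine(np.zeros(6, int), d, min_size=3)
        assert not pool
        assert len(set(refined)) == 1

    def test_conservation(self, rng):
        pts = rng.normal(size=20)
        d = _dist_from_points(pts)
        labels = mst_cluster(d, 6)
        refined, pool = refine(labels, d)
        assigned = [i for i in range(20) if refined[i] != UNASSIGNED]
        assert sorted(assigned + pool) == list(range(20))
        for lab in set(refined) - {UNASSIGNED}:
            assert np.count_nonzero(refined == lab) >= 3


class TestComputeTemplates:
    def test_mean_of_members(self):
        W = np.array([[1.0, 2.0], [3.0, 6.0], [5.0, 4.0]])
        F = np.array([[1.0], [3.0], [8.0]])
        labels = np.array([0, 0, 1])
        t = compute_templates(labels, W, F)
        np.testing.assert_allclose(t.waveforms[0], [2.0, 4.0])
        np.testing.assert_allclose(t.features[0], [2.0])
        np.testing.assert_allclose(t.waveforms[1], [5.0, 4.0])

    def test_scaled_pair_averages(self):
        x = np.arange(8.0)
        t = compute_templates(np.array([0, 0]), np.vstack([x, 3 * x]), np.ones((2, 3)))
        np.testing.assert_allclose(t.waveforms[0], 2 * x)

    def test_no_classes_rejected(self):
        with pytest.raises(ValueError):
            compute_templates(np.array([UNASSIGNED]), np.zeros((1, 4)), np.zeros((1, 2)))

    def test_ground_truth_recovery_noise_free(self, clean_recording):
        """Cluster templates of a noise-free record match the true waveforms."""
        from emgdecomp import decompose
        from emgdecomp.metrics import correlation_lag

        record, truth = clean_recording
        result = decompose(record)
        assert len(result.trains) == len(truth.templates)
        used = set()
        for tr in result.trains:
            best = max(
                (correlation_lag(tr.template, t.waveform)[0], t.mu_id)
                for t in truth.templates
                if t.mu_id not in used
            )
            assert best[0] >= 0.99
            used.add(best[1])
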