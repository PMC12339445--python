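"""Static and dynamic FC metrics against brute-force oracles."""

import itertools

import numpy as np
import pytest

from dynfc.metrics import (
    CommunitySequence,
    DynamicGraph,
    FCMetricSet,
    SlidingWindowSpec,
    average_metric_sets,
    binarize_dynamic,
    detect_communities,
    fc_variance,
    global_efficiency,
    node_cohesion,
    node_graph_metrics,
    sliding_window_fc,
    static_fc,
    temporal_correlation,
    window_weights,
)


class TestStaticFC:
    def test_duplicated_region_gives_clipped_fisher_z(self, rng):
        x = rng.standard_normal(200)
        data = np.column_stack([x, x, rng.standard_normal(200)])
        z = static_fc(data, fisher=True)
        assert z[0, 1] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_long_white_noise_decorrelates(self, rng):
        data = rng.standard_normal((10_000, 5))
        r = static_fc(data, fisher=False)
        iu = np.triu_indices(5, 1)
        assert np.abs(r[iu]).max() < 0.1

    def test_fisher_is_arctanh_of_plain_correlation(self, rng):
        data = rng.standard_normal((150, 6)).cumsum(axis=0)
        plain = static_fc(data, fisher=False)
        z = static_fc(data, fisher=True)
        iu = np.triu_indices(6, 1)
        np.testing.assert_allclose(z[iu], np.arctanh(plain[iu]), atol=1e-12)

    def test_zero_variance_region_flagged(self, rng):
        data = rng.standard_normal((50, 4))
        data[:, 2] = 1.0
        with pytest.raises(ValueError, match=r"\[2\]"):
            static_fc(data)


class TestSlidingWindows:
    def test_window_count_formula(self):
        # 1200 samples at TR 0.72 s = 864 s; 60 s windows sliding by 2 s
        spec = SlidingWindowSpec(window_length=60.0, step=2.0, taper_sigma=6.0, tr=0.72)
        assert spec.n_windows(1200) == 403

    def test_short_series_rejected(self):
        spec = SlidingWindowSpec(tr=0.72)
        with pytest.raises(ValueError, match="shorter"):
            sliding_window_fc(np.zeros((10, 3)), spec)

    def test_uniform_weight_limit_recovers_plain_pearson(self, rng):
        data = rng.standard_normal((90, 4))
        spec = SlidingWindowSpec(window_length=36.0, step=2.0, taper_sigma=1e6, tr=1.0)
        wfc = sliding_window_fc(data, spec)
        start, L = 0, 36
        expect = np.corrcoef(data[start : start + L], rowvar=False)
        np.testing.assert_allclose(wfc[0], expect, atol=1e-10)

    def test_stationary_series_windows_approximate_static_fc(self, rng):
        cov = np.array([[1, 0.6, 0.2], [0.6, 1, 0.4], [0.2, 0.4, 1.0]])
        data = rng.multivariate_normal(np.zeros(3), cov, size=4000)
        spec = SlidingWindowSpec(window_length=500.0, step=100.0, taper_sigma=20.0, tr=1.0)
        wfc = sliding_window_fc(data, spec)
        sfc = static_fc(data, fisher=False)
        np.fill_diagonal(sfc, 1.0)
        assert np.abs(wfc.mean(axis=0) - sfc).max() < 0.08

    def test_weights_normalised_and_positive(self):
        w = window_weights(SlidingWindowSpec())
        assert w.sum() == pytest.approx(1.0)
        assert np.all(w > 0)


class TestFCVariance:
    def test_identical_windows_give_zero(self):
        wfc = np.tile(np.eye(4) * 0.5, (6, 1, 1))
        np.testing.assert_array_equal(fc_variance(wfc), np.zeros((4, 4)))

    def test_two_window_hand_value(self):
        wfc = np.zeros((2, 2, 2))
        wfc[0, 0, 1] = wfc[0, 1, 0] = 0.2
        wfc[1, 0, 1] = wfc[1, 1, 0] = 0.6
        assert fc_variance(wfc)[0, 1] == pytest.approx(0.08)

    def test_matches_loop_oracle(self, rng):
        wfc = rng.random((5, 4, 4))
        wfc = (wfc + wfc.transpose(0, 2, 1)) / 2
        out = fc_variance(wfc)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                vals = [wfc[t, i, j] for t in range(5)]
                assert out[i, j] == pytest.approx(np.var(vals, ddof=1), abs=1e-14)

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            fc_variance(np.zeros((1, 3, 3)))


class TestBinarize:
    def test_exact_edge_count_small_density(self, rng):
        wfc = rng.random((7, 5, 5))
        g = binarize_dynamic(wfc, density=0.10)
        for t in range(7):
            assert g.adjacency[t].sum() // 2 == 1  # floor(0.1 * 10)

    def test_all_equal_values_pick_lexicographically_first_pairs(self):
        wfc = np.ones((2, 4, 4))
        g = binarize_dynamic(wfc, density=0.4)  # floor(0.4*6) = 2 edges
        for t in range(2):
            edges = {tuple(e) for e in np.argwhere(np.triu(g.adjacency[t], 1))}
            assert edges == {(0, 1), (0, 2)}

    def test_matches_sort_threshold_oracle(self, rng):
        wfc = rng.standard_normal((4, 6, 6))
        wfc = (wfc + wfc.transpose(0, 2, 1)) / 2
        g = binarize_dynamic(wfc, density=0.3)
        iu = np.triu_indices(6, 1)
        k = int(np.floor(0.3 * len(iu[0])))
        for t in range(4):
            vals = wfc[t][iu]
            top = set(np.argsort(-vals, kind="stable")[:k])
            got = {
                n
                for n, (i, j) in enumerate(zip(*iu))
                if g.adjacency[t, i, j]
            }
            assert got == top


class TestTemporalCorrelation:
    def test_constant_graph_gives_one(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        a[:, 0, 1] = a[:, 1, 0] = True
        a[:, 2, 3] = a[:, 3, 2] = True
        tc = temporal_correlation(DynamicGraph(adjacency=a, density=0.3))
        np.testing.assert_allclose(tc, 1.0)

    def test_disjoint_consecutive_edge_sets_give_zero(self):
        a = np.zeros((2, 4, 4), dtype=bool)
        a[0, 0, 1] = a[0, 1, 0] = True
        a[1, 2, 3] = a[1, 3, 2] = True
        tc = temporal_correlation(DynamicGraph(adjacency=a, density=0.2))
        np.testing.assert_allclose(tc, 0.0)

    def test_matches_per_term_loop_oracle(self, rng):
        a = rng.random((3, 4, 4)) > 0.5
        a = a | a.transpose(0, 2, 1)
        for t in range(3):
            np.fill_diagonal(a[t], False)
        tc = temporal_correlation(DynamicGraph(adjacency=a, density=0.5))
        W = 3
        for i in range(4):
            acc = 0.0
            for t in range(W - 1):
                num = sum(a[t, i, j] and a[t + 1, i, j] for j in range(4))
                den = np.sqrt(a[t, i].sum() * a[t + 1, i].sum())
                acc += num / den if den > 0 else 0.0
            assert tc[i] == pytest.approx(acc / (W - 1), abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        a = rng.random((6, 8, 8)) > 0.6
        a = a | a.transpose(0, 2, 1)
        for t in range(6):
            np.fill_diagonal(a[t], False)
        tc = temporal_correlation(DynamicGraph(adjacency=a, density=0.4))
        assert np.all((tc >= 0) & (tc <= 1))


def _two_clique_graph(W: int = 4) -> DynamicGraph:
    a = np.zeros((W, 8, 8), dtype=bool)
    for t in range(W):
        for grp in (range(4), range(4, 8)):
            for i, j in itertools.combinations(grp, 2):
                a[t, i, j] = a[t, j, i] = True
    return DynamicGraph(adjacency=a, density=0.4)


class TestCommunities:
    def test_persistent_cliques_keep_stable_labels(self):
        cs = detect_communities(_two_clique_graph(), seed=1)
        lab = cs.labels
        # two communities, constant in time
        assert len(set(lab[0])) == 2
        for t in range(1, 4):
            np.testing.assert_array_equal(lab[t], lab[0])

    def test_deterministic_given_seed(self, rng):
        a = rng.random((5, 10, 10)) > 0.7
        a = a | a.transpose(0, 2, 1)
        for t in range(5):
            np.fill_diagonal(a[t], False)
        g = DynamicGraph(adjacency=a, density=0.3)
        l1 = detect_communities(g, seed=7).labels
        l2 = detect_communities(g, seed=7).labels
        np.testing.assert_array_equal(l1, l2)

    def test_majority_overlap_keeps_label_on_partial_swap(self):
        g = _two_clique_graph(2)
        a = g.adjacency.copy()
        # window 1: node 3 defects from clique {0..3} to clique {4..7}
        a[1, 3, :] = False
        a[1, :, 3] = False
        for j in range(4, 8):
            a[1, 3, j] = a[1, j, 3] = True
        cs = detect_communities(DynamicGraph(adjacency=a, density=0.4), seed=0)
        lab = cs.labels
        # the majority of each clique keeps its window-0 label
        assert lab[1, 0] == lab[0, 0]
        assert lab[1, 4] == lab[0, 4]
        assert lab[1, 3] == lab[1, 4]  # defector joined the other community

    def test_isolated_nodes_become_singletons(self):
        a = np.zeros((2, 3, 3), dtype=bool)
        a[:, 0, 1] = a[:, 1, 0] = True
        cs = detect_communities(DynamicGraph(adjacency=a, density=0.3), seed=0)
        assert cs.labels[0, 2] not in (cs.labels[0, 0], cs.labels[0, 1])


class TestNodeCohesion:
    def test_constant_partition_gives_zero(self):
        labels = np.tile(np.array([0, 0, 1, 1]), (5, 1))
        nc = node_cohesion(CommunitySequence(labels=labels))
        np.testing.assert_array_equal(nc, 0)

    def test_single_joint_switch_counts_once(self):
        labels = np.array([[1, 1, 2], [2, 2, 2]])
        nc = node_cohesion(CommunitySequence(labels=labels))
        assert nc[0, 1] == 1
        assert nc[0, 2] == 0 and nc[1, 2] == 0

    def test_matches_triple_loop_oracle(self, rng):
        labels = rng.integers(0, 3, size=(6, 5))
        nc = node_cohesion(CommunitySequence(labels=labels))
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                count = 0
                for t in range(5):
                    if (
                        labels[t, i] == labels[t, j]
                        and labels[t + 1, i] == labels[t + 1, j]
                        and labels[t, i] != labels[t + 1, i]
                    ):
                        count += 1
                assert nc[i, j] == count
        assert nc.max() <= 5  # at most W-1 co-switches


class TestGraphMetrics:
    def test_complete_unit_graph_efficiency_is_one(self):
        m = np.ones((5, 5)) - np.eye(5)
        assert global_efficiency(m) == pytest.approx(1.0)

    def test_three_node_path_efficiency(self):
        m = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        assert global_efficiency(m) == pytest.approx(5 / 6)

    def test_efficiency_matches_floyd_warshall_oracle(self, rng):
        m = rng.random((8, 8)) * (rng.random((8, 8)) > 0.4)
        m = np.triu(m, 1)
        m = m + m.T
        d = np.where(m > 0, 1.0 / np.where(m > 0, m, 1), np.inf)
        np.fill_diagonal(d, 0.0)
        for k in range(8):
            for i in range(8):
                for j in range(8):
                    d[i, j] = min(d[i, j], d[i, k] + d[k, j])
        expect = np.mean(
            [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
             for i in range(8) for j in range(8) if i != j]
        )
        assert global_efficiency(m) == pytest.approx(expect, abs=1e-12)

    def test_star_graph_betweenness(self):
        m = np.zeros((5, 5))
        m[0, 1:] = m[1:, 0] = 1.0
        out = node_graph_metrics(m, kind="weights")
        assert out["betweenness"][0] == pytest.approx(1.0)
        np.testing.assert_allclose(out["betweenness"][1:], 0.0)

    def test_permutation_equivariance(self, rng):
        m = rng.random((6, 6)) * (rng.random((6, 6)) > 0.3)
        m = np.triu(m, 1)
        m = m + m.T
        perm = np.array([2, 0, 5, 1, 4, 3])
        base = node_graph_metrics(m)
        permuted = node_graph_metrics(m[np.ix_(perm, perm)])
        for key in ("degree", "betweenness", "closeness"):
            np.testing.assert_allclose(permuted[key], base[key][perm], atol=1e-12)

    def test_betweenness_matches_exhaustive_path_oracle(self, rng):
        n = 6
        m = rng.random((n, n)) * (rng.random((n, n)) > 0.3)
        m = np.triu(m, 1)
        m = m + m.T
        out = node_graph_metrics(m)
        dist = np.where(m > 0, 1.0 / np.where(m > 0, m, 1), np.inf)
        # enumerate all simple paths to find shortest-path structure
        best = {}
        for s in range(n):
            for t in range(n):
                if s >= t:
                    continue
                paths = []
                for k in range(n - 1):
                    for mid in itertools.permutations(
                        [v for v in range(n) if v not in (s, t)], k
                    ):
                        nodes = (s, *mid, t)
                        length = sum(
                            dist[a, b] for a, b in zip(nodes[:-1], nodes[1:])
                        )
                        if np.isfinite(length):
                            paths.append((length, nodes))
                if paths:
                    lmin = min(p[0] for p in paths)
                    best[(s, t)] = [p[1] for p in paths if p[0] <= lmin + 1e-12]
        bc = np.zeros(n)
        for (s, t), plist in best.items():
            for v in range(n):
                if v in (s, t):
                    continue
                frac = sum(v in p for p in plist) / len(plist)
                bc[v] += frac
        bc /= (n - 1) * (n - 2) / 2  # undirected normalisation
        np.testing.assert_allclose(out["betweenness"], bc, atol=1e-9)


class TestAveraging:
    def test_two_session_contract_is_elementwise_mean(self, rng):
        a = FCMetricSet(sfc=rng.random((4, 4)), fcv=rng.random((4, 4)),
                        tc=rng.random(4), nc=rng.random((4, 4)))
        b = FCMetricSet(sfc=rng.random((4, 4)), fcv=rng.random((4, 4)),
                        tc=rng.random(4), nc=rng.random((4, 4)))
        avg = average_metric_sets([a, b])
        np.testing.assert_allclose(avg.sfc, (a.sfc + b.sfc) / 2)
        np.testing.assert_allclose(avg.tc, (a.tc + b.tc) / 2)
        np.testing.assert_allclose(avg.nc, (a.nc + b.nc) / 2)
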