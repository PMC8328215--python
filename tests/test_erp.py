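"""Cluster statistics: adjacency construction, t-maps, cluster formation
against a brute-force oracle, permutation p-values, peak and amplitude
extraction."""

import numpy as np
import pytest

from deltaseg.containers import SensorLayout
from deltaseg.erp import (
    SensorAdjacency,
    build_adjacency,
    cluster_permutation_test,
    extract_peak,
    extract_single_trial_amplitude,
    find_clusters,
    paired_t_map,
)
from deltaseg.simulate import make_layout

from conftest import make_epochs


def square_layout(side=1.0):
    pos = np.array([[0, 0], [side, 0], [side, side], [0, side]], float)
    return SensorLayout(names=("A", "B", "C", "D"), positions=pos)


class TestAdjacency:
    def test_two_channels_single_edge(self):
        adj = build_adjacency(make_layout(2))
        assert adj.matrix.sum() == 2  # one symmetric edge

    def test_square_distance_threshold_gives_cycle(self):
        adj = build_adjacency(square_layout(), method="distance", threshold=1.0)
        assert adj.matrix.sum() == 8  # 4 edges, no diagonals
        assert not adj.matrix[0, 2] and not adj.matrix[1, 3]

    def test_symmetry_of_triangulation(self):
        adj = build_adjacency(make_layout(24))
        assert np.array_equal(adj.matrix, adj.matrix.T)
        assert not adj.matrix.diagonal().any()

    def test_duplicate_positions_rejected(self):
        lo = SensorLayout(names=("a", "b"), positions=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            build_adjacency(lo, method="distance", threshold=1.0)


class TestPairedTMap:
    def test_hand_computed_t(self):
        a = np.array([[[1.0]], [[2.0]], [[3.0]]])
        b = np.zeros((3, 1, 1))
        tm = paired_t_map(a, b, np.array([0.0]), ("E00",))
        assert tm.t[0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)))
        assert tm.df == 2

    def test_zero_difference_flagged_as_zero(self):
        a = np.ones((3, 2, 2))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            tm = paired_t_map(a, a, np.arange(2.0), ("E00", "E01"))
        assert (tm.t == 0).all()
        assert tm.degenerate.all()

    def test_constant_offset_gives_infinite_t_flag(self):
        a = np.ones((3, 1, 1))
        with pytest.warns(RuntimeWarning):
            tm = paired_t_map(a + 2.0, a, np.array([0.0]), ("E00",))
        assert np.isinf(tm.t[0, 0]) and tm.t[0, 0] > 0


def brute_force_clusters(t, threshold, adj, min_channels):
    """Independent oracle: exhaustive BFS over supra-threshold cells."""
    n_ch, n_t = t.shape
    out = []
    for sign in (+1, -1):
        cells = {(c, s) for c in range(n_ch) for s in range(n_t)
                 if np.isfinite(t[c, s]) and sign * t[c, s] > threshold}
        seen = set()
        for start in sorted(cells):
            if start in seen:
                continue
            comp, queue = set(), [start]
            while queue:
                c, s = queue.pop()
                if (c, s) in comp:
                    continue
                comp.add((c, s))
                for nb in [(c, s - 1), (c, s + 1)]:
                    if nb in cells and nb not in comp:
                        queue.append(nb)
                for c2 in range(n_ch):
                    if adj[c, c2] and (c2, s) in cells and (c2, s) not in comp:
                        queue.append((c2, s))
            seen |= comp
            if len({c for c, _ in comp}) >= min_channels:
                out.append((frozenset(comp),
                            float(sum(t[c, s] for c, s in comp))))
    return out


class TestFindClusters:
    def test_all_subthreshold_gives_empty_list(self):
        adj = build_adjacency(make_layout(4))
        from deltaseg.erp import TStatMap

        tm = TStatMap(t=np.zeros((4, 5)), df=7, times=np.arange(5.0),
                      ch_names=adj.names)
        assert find_clusters(tm, 2.0, adj) == []

    def test_min_channels_discards_single_channel_cluster(self):
        adj = build_adjacency(make_layout(4))
        from deltaseg.erp import TStatMap

        t = np.zeros((4, 10))
        t[2, :] = 5.0  # one channel, 10 samples
        tm = TStatMap(t=t, df=7, times=np.arange(10.0), ch_names=adj.names)
        assert find_clusters(tm, 2.0, adj, min_channels=3) == []
        assert len(find_clusters(tm, 2.0, adj, min_channels=1)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layout = make_layout(5)
        adj = build_adjacency(layout)
        from deltaseg.erp import TStatMap

        t = rng.normal(0, 2.0, size=(5, 20))
        tm = TStatMap(t=t, df=9, times=np.arange(20.0), ch_names=adj.names)
        got = find_clusters(tm, 1.5, adj, min_channels=1)
        expected = brute_force_clusters(t, 1.5, adj.matrix, 1)
        assert len(got) == len(expected)
        for members, mass in expected:
            match = [c for c in got
                     if frozenset(map(tuple, c.members)) == members]
            assert len(match) == 1
            assert match[0].mass == pytest.approx(mass)

    def test_masses_invariant_under_channel_relabeling(self):
        rng = np.random.default_rng(3)
        layout = make_layout(6)
        adj = build_adjacency(layout)
        t = rng.normal(0, 2.0, size=(6, 15))
        from deltaseg.erp import TStatMap

        perm = rng.permutation(6)
        adj_p = SensorAdjacency(
            names=tuple(adj.names[i] for i in perm),
            matrix=adj.matrix[np.ix_(perm, perm)],
        )
        tm = TStatMap(t=t, df=9, times=np.arange(15.0), ch_names=adj.names)
        tm_p = TStatMap(t=t[perm], df=9, times=np.arange(15.0),
                        ch_names=adj_p.names)
        masses = sorted(c.mass for c in find_clusters(tm, 1.5, adj))
        masses_p = sorted(c.mass for c in find_clusters(tm_p, 1.5, adj_p))
        assert np.allclose(masses, masses_p)


def _toy_dataset(rng, n_subj=6, n_ch=3, n_t=4, effect=0.0):
    layout = make_layout(n_ch)
    adj = build_adjacency(layout)
    a = rng.normal(0, 1.0, size=(n_subj, n_ch, n_t))
    b = rng.normal(0, 1.0, size=(n_subj, n_ch, n_t))
    a[:, :, 1:3] += effect
    times = np.arange(n_t) / 10.0
    return a, b, times, layout.names, adj


class TestClusterPermutationTest:
    def test_p_floor_is_two_over_n_perm_plus_one(self):
        rng = np.random.default_rng(0)
        # 12 participants: the chance of a sign-flip draw reproducing the
        # identity pattern (the only draw that can match the observed mass
        # at this effect size) is negligible
        a, b, times, names, adj = _toy_dataset(rng, n_subj=12, effect=30.0)
        res = cluster_permutation_test(
            a, b, times, names, adj, window=(0.0, 0.3), n_perm=200,
            min_channels=1, seed=1,
        )
        assert min(c.p for c in res.clusters) == pytest.approx(2 / 201)

    def test_p_monotone_in_mass_within_result(self):
        rng = np.random.default_rng(5)
        a, b, times, names, adj = _toy_dataset(rng, n_ch=5, n_t=12, effect=1.2)
        res = cluster_permutation_test(
            a, b, times, names, adj, window=(0.0, 1.2), n_perm=500,
            min_channels=1, seed=2,
        )
        pos = [c for c in res.clusters if c.sign > 0]
        for small, large in zip(pos[1:], pos[:-1]):
            assert large.p <= small.p
        assert all(c.p > 0 for c in res.clusters)

    def test_exhaustive_matches_monte_carlo(self):
        rng = np.random.default_rng(7)
        a, b, times, names, adj = _toy_dataset(rng, effect=1.5)
        kw = dict(window=(0.0, 0.3), min_channels=1)
        ex = cluster_permutation_test(a, b, times, names, adj,
                                      exhaustive=True, **kw)
        mc = cluster_permutation_test(a, b, times, names, adj, n_perm=4000,
                                      seed=3, **kw)
        assert len(ex.clusters) == len(mc.clusters)
        for ce, cm in zip(ex.clusters, mc.clusters):
            assert cm.p == pytest.approx(ce.p, abs=0.03)

    def test_exhaustive_rejected_above_16_participants(self):
        rng = np.random.default_rng(0)
        a, b, times, names, adj = _toy_dataset(rng, n_subj=17)
        with pytest.raises(ValueError):
            cluster_permutation_test(a, b, times, names, adj, exhaustive=True,
                                     window=(0.0, 0.3))


class TestPeakAndAmplitude:
    def _significant_result(self):
        rng = np.random.default_rng(1)
        a, b, times, names, adj = _toy_dataset(rng, n_ch=4, n_t=8, effect=4.0)
        return cluster_permutation_test(
            a, b, times, names, adj, window=(0.0, 0.8), n_perm=500,
            min_channels=1, seed=4,
        )

    def test_peak_is_max_abs_t_in_largest_cluster(self):
        res = self._significant_result()
        peak = extract_peak(res, +1)
        best = max(res.significant(+1), key=lambda c: abs(c.mass))
        vals = [abs(res.tmap.t[c, s]) for c, s in best.members]
        assert abs(res.tmap.t[peak.channel_index, peak.time_index]) == max(vals)

    def test_no_significant_cluster_gives_none(self):
        rng = np.random.default_rng(2)
        a, b, times, names, adj = _toy_dataset(rng, effect=0.0)
        res = cluster_permutation_test(
            a, b, times, names, adj, window=(0.0, 0.3), n_perm=200,
            min_channels=1, seed=5,
        )
        if not res.significant(+1):
            assert extract_peak(res, +1) is None

    def test_tie_breaks_lowest_channel_then_earliest_time(self):
        from deltaseg.erp import Cluster, ClusterTestResult, TStatMap

        t = np.full((2, 2), 3.0)
        tm = TStatMap(t=t, df=5, times=np.array([0.0, 0.1]),
                      ch_names=("E00", "E01"))
        members = np.array([[1, 1], [0, 1], [1, 0], [0, 0]])
        cl = Cluster(members=members, sign=+1, mass=12.0, p=0.01)
        res = ClusterTestResult(tmap=tm, clusters=[cl], n_perm=100, alpha=0.05,
                                window=(0, 0.1), seed=0, threshold=2.0)
        peak = extract_peak(res, +1)
        assert (peak.channel_index, peak.time_index) == (0, 0)

    def test_constant_trial_amplitude(self):
        ep = make_epochs(np.full((3, 2, 50), 7.0), 100.0, tmin=0.0)
        amp = extract_single_trial_amplitude(ep, "E01", 0.25)
        assert np.allclose(amp, 7.0)

    def test_window_mean_close_to_point_sample_on_smooth_data(self):
        rate = 100.0
        t = np.arange(100) / rate
        x = np.sin(2 * np.pi * 1.0 * t)  # slope bounded by 2*pi
        ep = make_epochs(np.tile(x, (2, 1, 1)), rate, tmin=0.0)
        a0 = extract_single_trial_amplitude(ep, "E00", 0.3, half_width=0.0)
        a1 = extract_single_trial_amplitude(ep, "E00", 0.3, half_width=0.01)
        assert np.abs(a0 - a1).max() < 2 * np.pi * (1 / rate)

    def test_unknown_channel_rejected(self):
        ep = make_epochs(np.zeros((1, 2, 50)), 100.0)
        with pytest.raises(KeyError):
            extract_single_trial_amplitude(ep, "nope", 0.1)
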