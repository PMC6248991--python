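"""DCCM contracts, betweenness oracle, Girvan–Newman communities."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from memdyn.dynamic_network import (
    DCCM,
    DynamicNetwork,
    build_network,
    connectivity_report,
    dccm,
    edge_betweenness,
    filter_communities,
    girvan_newman,
    modularity,
)
from memdyn.io_model import Topology, select

from conftest import anchored_system, make_trajectory


def brute_force_edge_betweenness(graph):
    """Exhaustive shortest-path enumeration (pure-python BFS, no nx algorithms)."""
    nodes = list(graph.nodes)
    adj = {n: sorted(graph.neighbors(n)) for n in nodes}
    counts = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s, t in itertools.combinations(nodes, 2):
        # BFS layering from s
        dist = {s: 0}
        frontier = [s]
        while frontier and t not in dist:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        if t not in dist:
            continue
        # enumerate all shortest paths by backtracking from t
        paths = []

        def back(node, path):
            if node == s:
                paths.append(path[::-1])
                return
            for u in adj[node]:
                if dist.get(u, -1) == dist[node] - 1:
                    back(u, path + [u])

        back(t, [t])
        w = 1.0 / len(paths)
        for path in paths:
            for a, b in zip(path, path[1:]):
                counts[tuple(sorted((a, b)))] += w
    return counts


def two_cliques_with_bridge():
    g = nx.Graph()
    for base in (0, 5):
        for a, b in itertools.combinations(range(base, base + 5), 2):
            g.add_edge(a, b)
    g.add_edge(4, 5)
    return g


class TestDccm:
    def _toy_corr_system(self):
        """Anchored system with two moving atoms sharing / opposing motion."""
        top, base, anchors, moving = anchored_system(3)
        rng = np.random.default_rng(0)
        s = rng.normal(size=(60, 3))
        disp = np.zeros((60, 7, 3))
        disp[:, 4, :] = s
        disp[:, 5, :] = s  # identical displacement -> c = 1
        disp[:, 6, :] = -s  # anti-phase -> c = -1
        traj = make_trajectory(base, disp, topology=top)
        return traj, anchors, moving

    def test_diagonal_exactly_one_symmetric_bounded(self, block_ensemble_factory):
        top, traj, _ = block_ensemble_factory(rho=0.9, n_frames=300)
        m = dccm(traj, select(top, "name CA"), stride_ps=None)
        assert np.all(np.diag(m.c) == 1.0)
        assert np.array_equal(m.c, m.c.T)
        assert m.c.min() >= -1.0 and m.c.max() <= 1.0

    def test_identical_and_antiphase_pairs(self):
        traj, anchors, moving = self._toy_corr_system()
        m = dccm(traj, moving, stride_ps=None, fit_selection=anchors)
        assert m.c[0, 1] > 1.0 - 1e-12
        assert m.c[0, 2] < -1.0 + 1e-12

    def test_planted_block_recovered_with_rigid_core_fit(
        self, block_ensemble_factory
    ):
        """Fitting on atoms outside the planted block recovers ρ=0.9."""
        top, traj, _ = block_ensemble_factory(rho=0.9, n_frames=20000, seed=2)
        sel = select(top, "name CA")
        fit = select(top, "name CA and not (segment TM2 or segment TM5)")
        m = dccm(traj, sel, stride_ps=None, fit_selection=fit)
        segs = np.asarray(m.segments)
        b2 = np.nonzero(segs == "TM2")[0]
        b5 = np.nonzero(segs == "TM5")[0]
        block_mean = m.c[np.ix_(b2, b5)].mean()
        assert 0.85 < block_mean < 0.95

    def test_zero_variance_atom_named_in_error(self):
        top, base, anchors, moving = anchored_system(2)
        disp = np.zeros((10, 6, 3))
        disp[:, 4, 0] = np.sin(np.arange(10))
        traj = make_trajectory(base, disp, topology=top)
        with pytest.raises(ValueError, match="zero-variance.*5"):
            dccm(traj, moving, stride_ps=None, fit_selection=anchors)

    def test_invariant_under_frame_duplication(self):
        traj, anchors, moving = self._toy_corr_system()
        m1 = dccm(traj, moving, stride_ps=None, fit_selection=anchors)
        doubled = make_trajectory(
            np.zeros_like(traj.coordinates[0]),
            np.tile(traj.coordinates, (2, 1, 1)),
            topology=traj.topology,
        )
        m2 = dccm(doubled, moving, stride_ps=None, fit_selection=anchors)
        assert np.allclose(m1.c, m2.c, atol=1e-12)


class TestBuildNetwork:
    def _dccm(self, c, resids=None, segments=None):
        n = c.shape[0]
        return DCCM(
            c=c,
            atom_indices=np.arange(n),
            resids=np.asarray(resids) if resids is not None else np.arange(0, 10 * n, 10),
            segments=np.asarray(segments, dtype=object) if segments is not None else None,
        )

    def test_identity_dccm_gives_edgeless_graph(self):
        g = build_network(self._dccm(np.eye(5)), cutoff=0.7)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 5

    def test_threshold_arithmetic_single_edge(self):
        c = np.eye(4)
        c[0, 2] = c[2, 0] = 0.75
        c[1, 3] = c[3, 1] = 0.55
        g = build_network(self._dccm(c), cutoff=0.7)
        assert set(g.edges) == {(0, 2)}
        assert g.edges[0, 2]["weight"] == pytest.approx(0.75)

    def test_sequence_separation_suppresses_neighbors(self):
        c = np.eye(3)
        c[0, 1] = c[1, 0] = 0.99
        g = build_network(self._dccm(c, resids=[5, 6, 9]), cutoff=0.7,
                          min_seq_separation=2)
        assert g.number_of_edges() == 0

    def test_anticorrelated_pairs_connect_via_absolute_value(self):
        c = np.eye(2)
        c[0, 1] = c[1, 0] = -0.8
        g = build_network(self._dccm(c), cutoff=0.7)
        assert g.number_of_edges() == 1

    def test_two_block_plant_has_dense_blocks(self, block_ensemble_factory):
        top, traj, _ = block_ensemble_factory(rho=0.9, n_frames=2000, seed=3)
        sel = select(top, "name CA")
        fit = select(top, "name CA and not (segment TM2 or segment TM5)")
        m = dccm(traj, sel, stride_ps=None, fit_selection=fit)
        g = build_network(m, cutoff=0.7)
        segs = np.asarray(m.segments)
        block = set(np.nonzero(np.isin(segs, ["TM2", "TM5"]))[0].tolist())
        within = sum(1 for u, v in g.edges if u in block and v in block)
        across = g.number_of_edges() - within
        assert within >= 10 * max(across, 1)

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            build_network(self._dccm(np.eye(3)), cutoff=0.0)


class TestBetweennessOracle:
    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        """Brandes accumulation equals exhaustive path enumeration, ≤12 nodes."""
        rng = np.random.default_rng(12345)
        for case in range(100):
            n = int(rng.integers(2, 13))
            p = float(rng.uniform(0.15, 0.8))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if g.number_of_edges() == 0:
                continue
            got = edge_betweenness(g)
            want = brute_force_edge_betweenness(g)
            assert set(got) == set(want)
            for e in want:
                assert got[e] == pytest.approx(want[e], abs=1e-9), (case, e)

    def test_bridge_betweenness_is_25(self):
        g = two_cliques_with_bridge()
        bt = edge_betweenness(g)
        assert bt[(4, 5)] == pytest.approx(25.0)
        assert bt[(4, 5)] == max(bt.values())


class TestGirvanNewman:
    def test_two_cliques_bridge_removed_first_and_q_by_hand(self):
        g = two_cliques_with_bridge()
        net = girvan_newman(g)
        assert sorted(map(sorted, net.communities)) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
        ]
        # hand-applied Newman-Girvan formula: e = (10/21, 10/21), a_k = 1/2 each
        q_hand = 2 * (10.0 / 21.0 - 0.25)
        assert net.final_q == pytest.approx(q_hand, abs=1e-12)
        # the bridge is the first removal: trace jumps to max Q at step 1
        assert net.modularity_trace[1] == pytest.approx(q_hand, abs=1e-12)

    def test_complete_graph_stays_one_community(self):
        net = girvan_newman(nx.complete_graph(6))
        assert len(net.communities) == 1
        assert net.final_q == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_graph_singleton_communities_q_zero(self):
        g = nx.empty_graph(4)
        net = girvan_newman(g)
        assert len(net.communities) == 4
        assert net.final_q == 0.0

    def test_partition_attains_max_of_trace(self):
        g = nx.les_miserables_graph()
        sub = g.subgraph(list(g.nodes)[:25]).copy()
        net = girvan_newman(sub)
        assert net.final_q == pytest.approx(max(net.modularity_trace))
        assert net.final_q >= modularity(sub, [set(sub.nodes)])

    def test_deterministic_trace_on_reruns(self):
        g = two_cliques_with_bridge()
        a, b = girvan_newman(g), girvan_newman(g)
        assert a.modularity_trace == b.modularity_trace
        assert a.communities == b.communities

    def test_modularity_matches_networkx(self):
        g = two_cliques_with_bridge()
        parts = [set(range(5)), set(range(5, 10))]
        assert modularity(g, parts) == pytest.approx(
            nx.algorithms.community.modularity(g, parts)
        )

    def test_planted_two_communities_ari_one_across_seeds(
        self, block_ensemble_factory
    ):
        """Planted-partition fixtures recovered exactly (ARI=1, 20 seeds)."""
        from sklearn.metrics import adjusted_rand_score

        from memdyn.synthetic import EnsembleSpec, make_bundle_reference, sample_ensemble

        top, ref = make_bundle_reference(7, 12)
        sel = select(top, "name CA")
        fit = select(
            top, "name CA and not (segment TM1 or segment TM2 or "
            "segment TM5 or segment TM6)"
        )
        for seed in range(20):
            spec = EnsembleSpec(
                topology=top, reference=ref, per_atom_sigma=0.5,
                correlation_blocks=[("TM1", "TM2", 0.9), ("TM5", "TM6", 0.9)],
                n_frames=1200, dt=100.0, seed=seed,
            )
            traj, _ = sample_ensemble(spec)
            m = dccm(traj, sel, stride_ps=None, fit_selection=fit)
            net = girvan_newman(build_network(m, cutoff=0.7))
            segs = np.asarray(m.segments)
            planted = np.where(np.isin(segs, ["TM1", "TM2"]), 0,
                               np.where(np.isin(segs, ["TM5", "TM6"]), 1, -1))
            node_comm = np.full(len(segs), -1)
            for k, comm in enumerate(net.communities):
                for n in comm:
                    node_comm[n] = k
            mask = planted >= 0
            assert adjusted_rand_score(planted[mask], node_comm[mask]) == 1.0


class TestReportingAndConnectivity:
    def _network_with_sizes(self, sizes, segments_per_comm):
        g = nx.Graph()
        communities = []
        node = 0
        for size, seg in zip(sizes, segments_per_comm):
            comm = set()
            for k in range(size):
                g.add_node(node, resid=node, segment=seg)
                comm.add(node)
                node += 1
            members = sorted(comm)
            for a, b in zip(members, members[1:]):
                g.add_edge(a, b, weight=0.9)
            communities.append(comm)
        return DynamicNetwork(
            graph=g, communities=communities,
            modularity_trace=[0.0], final_q=0.5,
        )

    def test_min_size_filter_reports_two_of_three(self):
        net = self._network_with_sizes([25, 12, 4], ["TM1", "TM2", "TM3"])
        view = filter_communities(net, 10)
        assert len(view.reported_communities) == 2
        assert len(view.communities) == 3  # partition unchanged

    def test_min_size_one_reports_all(self):
        net = self._network_with_sizes([25, 12, 4], ["TM1", "TM2", "TM3"])
        assert len(filter_communities(net, 1).reported_communities) == 3

    def test_all_filtered_warns_not_errors(self):
        net = self._network_with_sizes([4, 3], ["TM1", "TM2"])
        with pytest.warns(UserWarning, match="no communities"):
            view = filter_communities(net, 10)
        assert view.reported_communities == []

    def test_same_segment_true_iff_hosts_reported_community(self):
        net = self._network_with_sizes([15, 4], ["TM2", "TM5"])
        view = filter_communities(net, 10)
        assert connectivity_report(view, "TM2", "TM2")[0] is True
        assert connectivity_report(view, "TM5", "TM5")[0] is False

    def test_inter_community_edge_connects_segments(self):
        net = self._network_with_sizes([12, 12], ["TM2", "TM5"])
        net.graph.add_edge(0, 12, weight=0.8)  # bridge between the communities
        view = filter_communities(net, 10)
        ok, support = connectivity_report(view, "TM2", "TM5")
        assert ok is True
        assert (0, 12) in support

    def test_unknown_segment_rejected(self):
        net = self._network_with_sizes([12], ["TM2"])
        with pytest.raises(ValueError, match="TM7"):
            connectivity_report(net, "TM2", "TM7")

    def test_planted_functional_vs_null_connectivity(self, block_ensemble_factory):
        """End-to-end: planted TM2-TM5 coupling is declared connected, the
        null plant is not."""
        top, traj, _ = block_ensemble_factory(rho=0.9, n_frames=1200, seed=4)
        sel = select(top, "name CA")
        m = dccm(traj, sel, stride_ps=100.0)
        net = filter_communities(girvan_newman(build_network(m, 0.7)), 10)
        assert connectivity_report(net, "TM2", "TM5")[0] is True

        top0, traj0, _ = block_ensemble_factory(rho=None, n_frames=1200, seed=4)
        m0 = dccm(traj0, sel, stride_ps=100.0)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            net0 = filter_communities(girvan_newman(build_network(m0, 0.7)), 10)
        assert connectivity_report(net0, "TM2", "TM5")[0] is False
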