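import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from lidflex.correlation import CorrelationMatrix
from lidflex.io import Ensemble, RegionDefinition, select
from lidflex.network import (
    DynamicalNetwork, build_network, contact_persistence, edge_betweenness,
    girvan_newman_communities, intercommunity_flow, pocket_residues,
)
from .conftest import make_structure


def brute_force_edge_betweenness(graph):
    """Independent all-pairs edge betweenness via Floyd-Warshall + path DP.

    For each ordered source-target pair, the fraction of shortest paths
    through each edge is sigma_s(u) * sigma(v->t) / sigma_st whenever the
    edge lies on a shortest path. Undirected pair convention matches
    networkx's unnormalized edge betweenness.
    """
    nodes = sorted(graph.nodes)
    idx = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    w = np.full((n, n), np.inf)
    for u, v, d in graph.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = d.get("weight", 1.0)
    dist = floyd_warshall(w)
    # sigma[s, t]: number of shortest s->t paths
    sigma = np.zeros((n, n))
    for s in range(n):
        order = np.argsort(dist[s])
        sigma[s, s] = 1.0
        for t in order:
            if t == s or np.isinf(dist[s, t]):
                continue
            total = 0.0
            for u in range(n):
                if np.isfinite(w[u, t]) and np.isclose(
                        dist[s, u] + w[u, t], dist[s, t], atol=1e-12):
                    total += sigma[s, u]
            sigma[s, t] = total
    eb = {tuple(sorted(e)): 0.0 for e in graph.edges}
    for s in range(n):
        for t in range(n):
            if s >= t or sigma[s, t] == 0:
                continue
            for u, v in graph.edges:
                iu, iv = idx[u], idx[v]
                for a, b in ((iu, iv), (iv, iu)):
                    if np.isclose(dist[s, a] + w[a, b] + dist[b, t],
                                  dist[s, t], atol=1e-12):
                        eb[tuple(sorted((u, v)))] += \
                            sigma[s, a] * sigma[b, t] / sigma[s, t]
    return eb


def net_from_graph(g):
    return DynamicalNetwork(graph=g, residue_ids=np.array(sorted(g.nodes)),
                            persistence_cutoff=0.0, distance_cutoff=0.0)


class TestContactPersistence:
    def fixture_ensemble(self, separations):
        """Two single-atom residues at given per-frame separations."""
        s = make_structure([
            ("A", 1, "ALA", "CA", "C", (0.0, 0.0, 0.0)),
            ("A", 5, "ALA", "CA", "C", (1.0, 0.0, 0.0)),
        ])
        frames = np.zeros((len(separations), 2, 3))
        frames[:, 1, 0] = separations
        return s, Ensemble(topology=s, frames=frames)

    def test_permanent_contact_is_one(self):
        s, ens = self.fixture_ensemble([3.0] * 4)
        cmap = contact_persistence(ens, RegionDefinition("a", (1,)),
                                   RegionDefinition("b", (5,)), cutoff=4.5)
        assert cmap[(1, 5)] == 1.0

    def test_never_in_contact_is_zero(self):
        s, ens = self.fixture_ensemble([9.0] * 4)
        cmap = contact_persistence(ens, RegionDefinition("a", (1,)),
                                   RegionDefinition("b", (5,)), cutoff=4.5)
        assert cmap[(1, 5)] == 0.0

    def test_seven_of_ten_frames(self):
        seps = [3.0] * 7 + [9.0] * 3
        s, ens = self.fixture_ensemble(seps)
        cmap = contact_persistence(ens, RegionDefinition("a", (1,)),
                                   RegionDefinition("b", (5,)), cutoff=4.5)
        assert cmap[(1, 5)] == pytest.approx(0.7)

    def test_frame_order_invariant(self):
        seps = [3.0, 9.0, 3.0, 9.0, 3.0]
        s, ens1 = self.fixture_ensemble(seps)
        s2, ens2 = self.fixture_ensemble(seps[::-1])
        a = contact_persistence(ens1, RegionDefinition("a", (1,)),
                                RegionDefinition("b", (5,)), cutoff=4.5)
        b = contact_persistence(ens2, RegionDefinition("a", (1,)),
                                RegionDefinition("b", (5,)), cutoff=4.5)
        assert a.fractions == b.fractions

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            RegionDefinition("empty", ())


class TestPocketResidues:
    def make_complex(self, distances):
        atoms = [("A", 900, "LIG", "C1", "C", (0.0, 0.0, 0.0))]
        for i, d in enumerate(distances):
            atoms.insert(i, ("A", i + 1, "ALA", "CA", "C", (d, 0.0, 0.0)))
        s = make_structure(atoms)
        s.is_hetero[-1] = True
        return s

    def test_boundary_inside_and_outside(self):
        s = self.make_complex([4.9, 5.1])
        region = pocket_residues(s, select(s, "ligand"), radius=5.0)
        assert region.residues == (1,)

    def test_designed_pocket_recovered(self):
        s = self.make_complex([3.0, 4.0, 4.9, 8.0, 12.0])
        region = pocket_residues(s, select(s, "ligand"), radius=5.0)
        assert region.residues == (1, 2, 3)


class TestBuildNetwork:
    def contact_ensemble(self):
        """5 single-atom residues in a line, 4 A spacing, static."""
        coords = np.array([[i * 4.0, 0, 0] for i in range(5)])
        s = make_structure([
            ("A", i + 1, "ALA", "CA", "C", tuple(coords[i])) for i in range(5)
        ])
        frames = np.repeat(coords[None], 4, axis=0)
        return s, Ensemble(topology=s, frames=frames)

    def corr(self, n, value):
        v = np.full((n, n), float(value))
        np.fill_diagonal(v, 1.0)
        return CorrelationMatrix(values=v, residue_ids=np.arange(1, n + 1))

    def test_weights_are_minus_log_correlation(self):
        s, ens = self.contact_ensemble()
        net = build_network(ens, self.corr(5, 0.5), persistence_cutoff=0.5,
                            distance_cutoff=8.5, atom_level="ca")
        # |i-j| == 1 excluded; 4 A spacing puts |i-j| == 2 within 8.5 A
        assert net.graph.has_edge(1, 3)
        assert not net.graph.has_edge(1, 2)
        assert net.graph[1][3]["weight"] == pytest.approx(-np.log(0.5))

    def test_perfect_correlation_clamped_to_tiny_weight(self):
        s, ens = self.contact_ensemble()
        net = build_network(ens, self.corr(5, 1.0 - 1e-12),
                            persistence_cutoff=0.5, distance_cutoff=8.5,
                            atom_level="ca")
        assert 0 < net.graph[1][3]["weight"] < 1.1e-6

    def test_weight_monotone_in_correlation(self):
        s, ens = self.contact_ensemble()
        weights = []
        for c in (0.2, 0.5, 0.9):
            net = build_network(ens, self.corr(5, c), persistence_cutoff=0.5,
                                distance_cutoff=8.5, atom_level="ca")
            weights.append(net.graph[1][3]["weight"])
        assert weights[0] > weights[1] > weights[2]


class TestTwoDomainENM:
    def test_bridge_edge_carries_highest_betweenness(self):
        """Two 10-node domains joined by one close residue pair: every
        cross-domain shortest path uses the bridge edge."""
        from lidflex import enm
        from lidflex.correlation import dccm as dccm_fn

        a = enm.make_compact_cluster(10, first_resid=1)
        b = enm.make_compact_cluster(10, first_resid=11)
        b.coords[:] = b.coords + np.array([12.0, 0.0, 0.0])
        atoms = [("A", int(r), "ALA", "CA", "C", tuple(c))
                 for r, c in zip(
                     np.concatenate([a.res_ids, b.res_ids]),
                     np.vstack([a.coords, b.coords]))]
        s = make_structure(atoms)
        model = enm.build_enm(s, cutoff=13.0, gamma=5.0)
        ens = enm.sample_ensemble(model, 400, seed=31)
        c = dccm_fn(ens, select(s, "ca"))
        # pick the contact cutoff so exactly one cross-domain pair connects
        d = np.linalg.norm(s.coords[:, None] - s.coords[None], axis=-1)
        cross = d[:10, 10:]
        cutoff = (np.sort(cross.ravel())[0] + np.sort(cross.ravel())[1]) / 2
        net = build_network(ens, c, persistence_cutoff=0.75,
                            distance_cutoff=float(cutoff), atom_level="ca")
        assert nx.is_connected(net.graph)
        eb = edge_betweenness(net.graph)
        bridge = max(eb, key=eb.get)
        assert (bridge[0] <= 10) != (bridge[1] <= 10)
        oracle = brute_force_edge_betweenness(net.graph)
        for e in eb:
            assert eb[e] == pytest.approx(oracle[e], abs=1e-9)


class TestGirvanNewman:
    def two_cliques(self):
        g = nx.Graph()
        for base in (0, 6):
            for i in range(6):
                for j in range(i + 1, 6):
                    g.add_edge(base + i, base + j, weight=1.0)
        g.add_edge(0, 6, weight=1.0)  # the bridge
        return g

    def test_bridge_has_maximal_betweenness(self):
        g = self.two_cliques()
        eb = edge_betweenness(g)
        oracle = brute_force_edge_betweenness(g)
        assert max(eb, key=eb.get) == (0, 6)
        for e, v in eb.items():
            assert v == pytest.approx(oracle[e], abs=1e-9)

    def test_two_cliques_split_into_two_communities(self):
        net = net_from_graph(self.two_cliques())
        net = girvan_newman_communities(net)
        comms = net.communities()
        assert sorted(map(sorted, comms)) == [list(range(6)),
                                              list(range(6, 12))]

    def test_complete_graph_single_community(self):
        g = nx.complete_graph(8)
        nx.set_edge_attributes(g, 1.0, "weight")
        net = girvan_newman_communities(net_from_graph(g))
        assert len(set(net.partition.values())) == 1

    def test_planted_three_block_recovery(self):
        rng = np.random.default_rng(9)
        g = nx.Graph()
        g.add_nodes_from(range(36))
        truth = {i: i // 12 for i in range(36)}
        for i in range(36):
            for j in range(i + 1, 36):
                p = 0.9 if truth[i] == truth[j] else 0.05
                if rng.random() < p:
                    g.add_edge(i, j, weight=1.0)
        net = girvan_newman_communities(net_from_graph(g))
        labels = [net.partition[i] for i in range(36)]
        # adjusted Rand index against the planted labels
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(list(truth.values()), labels) == 1.0

    def test_betweenness_matches_brute_force_on_weighted_graph(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(14, 0.35, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = float(rng.uniform(0.5, 2.0))
        eb = edge_betweenness(g)
        oracle = brute_force_edge_betweenness(g)
        for e in eb:
            assert eb[e] == pytest.approx(oracle[e], abs=1e-9)

    def test_k_requested_communities(self):
        net = net_from_graph(self.two_cliques())
        net = girvan_newman_communities(net, k=2)
        assert len(set(net.partition.values())) == 2

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            girvan_newman_communities(net_from_graph(nx.Graph()))


class TestIntercommunityFlow:
    def test_no_cross_edges_zero_flow(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=1.0)
        g.add_edge(2, 3, weight=1.0)
        net = net_from_graph(g)
        flow = intercommunity_flow(net, partition={0: 0, 1: 0, 2: 1, 3: 1})
        assert flow == {}

    def test_bridge_flow_equals_bridge_betweenness(self):
        g = TestGirvanNewman().two_cliques()
        net = net_from_graph(g)
        part = {n: 0 if n < 6 else 1 for n in g.nodes}
        flow = intercommunity_flow(net, partition=part)
        eb = edge_betweenness(g)
        assert flow[(0, 1)] == pytest.approx(eb[(0, 6)])

    def test_total_betweenness_conserved_under_merging(self):
        g = TestGirvanNewman().two_cliques()
        eb = edge_betweenness(g)
        total = sum(eb.values())
        net = net_from_graph(g)
        part3 = {n: (0 if n < 3 else 1 if n < 6 else 2) for n in g.nodes}
        flow3 = intercommunity_flow(net, partition=part3)
        part2 = {n: (0 if n < 6 else 1) for n in g.nodes}
        flow2 = intercommunity_flow(net, partition=part2)
        intra3 = total - sum(flow3.values())
        intra2 = total - sum(flow2.values())
        # merging 0 and 1 moves their mutual flow into the intra budget
        assert intra2 == pytest.approx(intra3 + flow3[(0, 1)])

    def test_normalized_flow_sums_below_one(self):
        g = TestGirvanNewman().two_cliques()
        net = net_from_graph(g)
        part = {n: 0 if n < 6 else 1 for n in g.nodes}
        flow = intercommunity_flow(net, partition=part, normalized=True)
        assert 0 < sum(flow.values()) <= 1.0


class TestCommunityCoupling:
    def test_weaker_coupling_more_communities(self):
        """Two blocks whose cross-edges carry tunable correlation strength:
        weakly coupled blocks split apart, strongly coupled ones merge."""
        def blocks(cross_strength):
            g = nx.Graph()
            for base in (0, 8):
                for i in range(8):
                    for j in range(i + 1, 8):
                        g.add_edge(base + i, base + j, weight=1.0,
                                   strength=1.0)
            for b in range(4):
                g.add_edge(b, 8 + b, weight=1.0 / cross_strength,
                           strength=cross_strength)
            return net_from_graph(g)

        weak = girvan_newman_communities(blocks(0.1))
        strong = girvan_newman_communities(blocks(30.0))
        assert len(set(weak.partition.values())) == 2
        assert len(set(strong.partition.values())) == 1
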