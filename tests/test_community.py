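import numpy as np
import pytest

from idnet import LagNetwork, modularity, spinglass_communities
from idnet.community import signed_hamiltonian
from oracles import modularity_direct


def _net(W, nodes=None):
    W = np.asarray(W, dtype=float)
    nodes = nodes or [f"n{i}" for i in range(W.shape[0])]
    return LagNetwork(nodes=nodes, W=W)


def _two_clique_net(bridge=0.1):
    """Two 4-node positive cliques joined by one weak edge."""
    W = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    W[3, 4] = W[4, 3] = bridge
    return _net(W)


class TestModularity:
    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            W = rng.normal(0, 0.4, (5, 5)) * (rng.random((5, 5)) < 0.5)
            labels = rng.integers(0, 3, 5)
            net = _net(W)
            assert modularity(net, labels) == pytest.approx(
                modularity_direct(W, labels), abs=1e-12)

    def test_three_node_ring_by_hand(self):
        # positive ring 0->1 (w=1), 1->2 (w=2), 2->0 (w=0.5); m = 3.5
        # sout = (1,2,.5), sin = (.5,1,2).
        # One community: Q = (m - (Σsout)(Σsin)/m)/m = 0 exactly.
        W = np.zeros((3, 3))
        W[0, 1], W[1, 2], W[2, 0] = 1.0, 2.0, 0.5
        net = _net(W)
        assert modularity(net, np.zeros(3, dtype=int)) == pytest.approx(0.0, abs=1e-12)
        # communities {0} and {1,2}: within-weight = w(1,2) = 2; null sum
        # over same-community pairs = .5 + 2 + 4 + .5 + 1 = 8
        # Q = (2 - 8/3.5)/3.5 = -4/49
        assert modularity(net, np.array([0, 1, 1])) == pytest.approx(-4 / 49, abs=1e-12)

    def test_planted_two_block_positive(self):
        net = _two_clique_net()
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert modularity(net, labels) > 0

    def test_relabeling_invariance(self):
        net = _two_clique_net()
        a = modularity(net, np.array([0, 0, 0, 0, 1, 1, 1, 1]))
        b = modularity(net, np.array([5, 5, 5, 5, 2, 2, 2, 2]))
        assert a == pytest.approx(b, abs=1e-14)

    def test_random_membership_near_zero_mean(self):
        rng = np.random.default_rng(1)
        W = rng.normal(0, 0.4, (10, 10)) * (rng.random((10, 10)) < 0.4)
        np.fill_diagonal(W, 0.0)  # self-loops bias Q under random labels
        net = _net(W)
        qs = [modularity(net, np.random.default_rng(s).integers(0, 3, 10))
              for s in range(100)]
        assert abs(np.mean(qs)) < 0.05

    def test_missing_node_rejected(self):
        with pytest.raises(ValueError, match="membership"):
            modularity(_net(np.eye(3)), {"n0": 0, "n1": 0})


class TestSpinglass:
    def test_planted_partition_recovered(self):
        net = _two_clique_net()
        recovered = 0
        for seed in range(15):
            res = spinglass_communities(net, seed=seed, n_restarts=3)
            m = np.array([res.membership[n] for n in net.nodes])
            ok = (len(set(m[:4])) == 1 and len(set(m[4:])) == 1
                  and m[0] != m[4])
            recovered += ok
        assert recovered >= 15 * 0.95 - 1e-9

    def test_uniform_complete_graph_single_community(self):
        W = np.full((6, 6), 0.5)
        np.fill_diagonal(W, 0.0)
        res = spinglass_communities(_net(W), seed=0, n_restarts=5)
        assert len(set(res.membership.values())) == 1

    def test_hamiltonian_consistent_with_membership(self):
        net = _two_clique_net()
        res = spinglass_communities(net, seed=3, n_restarts=3)
        assert res.hamiltonian == pytest.approx(
            signed_hamiltonian(net, res.membership), abs=1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        W = rng.normal(0, 0.4, (9, 9)) * (rng.random((9, 9)) < 0.4)
        net = _net(W)
        r1 = spinglass_communities(net, seed=42, n_restarts=4)
        r2 = spinglass_communities(net, seed=42, n_restarts=4)
        assert r1.membership == r2.membership
        assert r1.hamiltonian == r2.hamiltonian
        assert r1.modularity == r2.modularity

    def test_community_ids_contiguous(self):
        rng = np.random.default_rng(4)
        W = rng.normal(0, 0.4, (8, 8)) * (rng.random((8, 8)) < 0.3)
        res = spinglass_communities(_net(W), seed=0, n_restarts=3)
        ids = sorted(set(res.membership.values()))
        assert ids == list(range(len(ids)))

    def test_disconnected_components_handled(self):
        W = np.zeros((5, 5))
        W[0, 1] = W[1, 0] = 1.0
        W[2, 3] = W[3, 2] = 1.0   # node 4 isolated
        res = spinglass_communities(_net(W), seed=0, n_restarts=3)
        m = res.membership
        assert m["n0"] == m["n1"]
        assert m["n2"] == m["n3"]
        assert len({m["n0"], m["n2"], m["n4"]}) == 3

    def test_beats_random_memberships_on_planted_network(self):
        net = _two_clique_net()
        res = spinglass_communities(net, seed=1, n_restarts=3)
        q_best = res.modularity
        k = len(set(res.membership.values()))
        rng = np.random.default_rng(0)
        q_rand = [modularity(net, rng.integers(0, k, net.p)) for _ in range(100)]
        assert q_best >= max(q_rand) - 1e-12

    def test_agrees_with_igraph_on_positive_planted_graph(self):
        igraph = pytest.importorskip("igraph")
        net = _two_clique_net()
        res = spinglass_communities(net, seed=0, n_restarts=3)
        edges, weights = [], []
        for i in range(net.p):
            for j in range(i + 1, net.p):
                if net.W[i, j] != 0:
                    edges.append((i, j))
                    weights.append(net.W[i, j])
        g = igraph.Graph(n=net.p, edges=edges)
        ref = g.community_spinglass(weights=weights, spins=8)
        ours = [res.membership[n] for n in net.nodes]
        # same partition up to relabeling
        assert len(set(zip(ours, ref.membership))) == len(set(ours))
        assert len(set(ours)) == len(set(ref.membership))
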