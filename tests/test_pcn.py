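import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.metrics import adjusted_rand_score

from oligotopo import pcn
from oligotopo.pcn import (
    ContactNetwork,
    DisconnectedError,
    NetworkError,
    betweenness,
    build_network,
    cluster_color_map,
    fiedler_vector,
    interchain_pairing,
    spectral_clusters,
)
from oligotopo.structio import calpha_coordinates
from oligotopo.synthetic import gen_bead_trimer


def net_from_adjacency(A, chains=None):
    n = len(A)
    if chains is None:
        nodes = [("A", i + 1) for i in range(n)]
    else:
        nodes = [(chains[i], i + 1) for i in range(n)]
    return ContactNetwork(nodes=nodes, adjacency=np.asarray(A))


def brute_force_betweenness(A):
    """Independent oracle: BFS + explicit shortest-path enumeration."""
    A = np.asarray(A)
    n = len(A)
    neighbors = [np.flatnonzero(A[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        # BFS from s
        dist = [-1] * n
        dist[s] = 0
        queue = [s]
        while queue:
            u = queue.pop(0)
            for v in neighbors[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        if dist[t] < 0:
            continue
        # enumerate every shortest path s -> t by backtracking from t
        paths = []

        def back(v, acc):
            if v == s:
                paths.append(acc)
                return
            for u in neighbors[v]:
                if dist[u] == dist[v] - 1:
                    back(u, acc + [u])

        back(t, [])
        total = len(paths)
        for path in paths:
            for v in path:  # interior nodes only (s excluded, t never in acc)
                if v != s:
                    bc[v] += 1.0 / total
    return bc


def random_graph(n, p, seed):
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                A[i, j] = A[j, i] = 1
    return A


def planted_blocks(sizes, p_in, p_out, seed):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    n = len(labels)
    A = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            p = p_in if labels[i] == labels[j] else p_out
            if rng.random() < p:
                A[i, j] = A[j, i] = 1
    return A, labels


class TestBuildNetwork:
    def test_one_edge_at_5A(self):
        net, _ = build_network([("A", 1, np.zeros(3)), ("A", 5, np.array([5.0, 0, 0]))])
        assert net.adjacency.sum() == 2

    def test_consecutive_residues_excluded(self):
        net, _ = build_network([("A", 1, np.zeros(3)), ("A", 2, np.array([3.8, 0, 0]))])
        assert net.adjacency.sum() == 0

    def test_boundary_distances_excluded(self):
        cal = [
            ("A", 1, np.zeros(3)),
            ("A", 5, np.array([4.0, 0, 0])),
            ("A", 9, np.array([-8.0, 0, 0])),
        ]
        net, _ = build_network(cal)
        assert net.adjacency[0, 1] == 0  # exactly 4 Å
        assert net.adjacency[0, 2] == 0  # exactly 8 Å

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(50)
        pts = rng.uniform(0, 20, size=(50, 3))
        cal = [("A", i + 1, pts[i]) for i in range(50)]
        net, _ = build_network(cal)
        expect = np.zeros((50, 50), dtype=int)
        for i in range(50):
            for j in range(50):
                if i == j:
                    continue
                d = np.linalg.norm(pts[i] - pts[j])
                if 4.0 < d < 8.0:
                    expect[i, j] = 1
        np.testing.assert_array_equal(net.adjacency, expect)

    def test_bad_cutoffs(self):
        cal = [("A", 1, np.zeros(3)), ("A", 2, np.ones(3))]
        with pytest.raises(NetworkError):
            build_network(cal, lower_cut=8, upper_cut=4)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 15, size=(30, 3))
        R = Rotation.from_euler("xyz", [1.0, 0.3, -0.8]).as_matrix()
        cal1 = [("A", i + 1, pts[i]) for i in range(30)]
        cal2 = [("A", i + 1, pts[i] @ R.T + np.array([7.0, 1.0, -4.0])) for i in range(30)]
        n1, _ = build_network(cal1)
        n2, _ = build_network(cal2)
        np.testing.assert_array_equal(n1.adjacency, n2.adjacency)

    def test_laplacian_invariants(self):
        A = random_graph(15, 0.3, seed=1)
        net = net_from_adjacency(A)
        L = net.laplacian
        np.testing.assert_array_equal(L.sum(axis=1), np.zeros(15))
        eigvals = np.linalg.eigvalsh(L.astype(float))
        assert eigvals[0] == pytest.approx(0.0, abs=1e-10)
        assert np.all(eigvals > -1e-10)


class TestFiedler:
    def test_path3_analytic(self):
        # L(P3) spectrum is {0, 1, 3}; v2 ∝ (1, 0, -1)/√2
        net = net_from_adjacency([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        v2, lam = fiedler_vector(net)
        assert lam == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(v2, [1 / np.sqrt(2), 0, -1 / np.sqrt(2)], atol=1e-10)

    def test_two_cliques_one_bridge(self):
        n = 5
        A = np.zeros((2 * n, 2 * n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            A[i, j] = A[j, i] = 1
            A[n + i, n + j] = A[n + j, n + i] = 1
        A[n - 1, n] = A[n, n - 1] = 1
        net = net_from_adjacency(A)
        v2, lam = fiedler_vector(net)
        assert lam > 0
        signs = np.sign(v2)
        assert len(set(signs[:n])) == 1
        assert len(set(signs[n:])) == 1
        assert signs[0] != signs[-1]

    def test_disconnected_error(self):
        A = np.zeros((6, 6), dtype=int)
        for offs in (0, 3):
            for i, j in itertools.combinations(range(3), 2):
                A[offs + i, offs + j] = A[offs + j, offs + i] = 1
        with pytest.raises(DisconnectedError, match="disconnected"):
            fiedler_vector(net_from_adjacency(A))

    def test_unit_norm_and_orthogonal_to_ones(self):
        A = random_graph(12, 0.4, seed=3)
        net = net_from_adjacency(A)
        v2, _ = fiedler_vector(net)
        assert np.linalg.norm(v2) == pytest.approx(1.0, abs=1e-10)
        assert abs(v2.sum()) < 1e-8

    def test_sign_convention(self):
        A = random_graph(10, 0.6, seed=5)
        v2, _ = fiedler_vector(net_from_adjacency(A))
        nz = v2[np.abs(v2) > 1e-12]
        assert nz[0] > 0


class TestSpectralClusters:
    def test_planted_three_blocks_exact(self):
        A, labels = planted_blocks([30, 30, 30], 0.5, 0.02, seed=7)
        net = net_from_adjacency(A)
        part = spectral_clusters(net, k=3, seed=0)
        assert adjusted_rand_score(labels, part.labels) == 1.0

    def test_planted_blocks_k2_merges(self):
        A, labels = planted_blocks([30, 30, 30], 0.5, 0.02, seed=7)
        part = spectral_clusters(net_from_adjacency(A), k=2, seed=0)
        best = 0.0
        for a, b in itertools.combinations(range(3), 2):
            merged = labels.copy()
            merged[merged == b] = a
            best = max(best, adjusted_rand_score(merged, part.labels))
        assert best >= 0.9

    def test_symmetric_barbell_equal_halves(self):
        n = 6
        A = np.zeros((2 * n, 2 * n), dtype=int)
        for i, j in itertools.combinations(range(n), 2):
            A[i, j] = A[j, i] = 1
            A[n + i, n + j] = A[n + j, n + i] = 1
        A[n - 1, n] = A[n, n - 1] = 1
        part = spectral_clusters(net_from_adjacency(A), k=2, seed=0)
        counts = np.bincount(part.labels)
        assert counts.tolist() == [n, n]

    def test_bead_trimer_k3_recovers_chains(self):
        bt = gen_bead_trimer(40, {("A", "B"): 6, ("A", "C"): 6, ("B", "C"): 6}, seed=17)
        cal = calpha_coordinates(bt.model)
        net, _ = build_network(cal)
        part = spectral_clusters(net, k=3, seed=0)
        assert adjusted_rand_score(bt.planted_labels, part.labels) >= 0.9

    def test_canonical_labels(self):
        A, _ = planted_blocks([10, 10, 10], 0.9, 0.02, seed=2)
        part = spectral_clusters(net_from_adjacency(A), k=3, seed=0)
        assert part.labels[0] == 0  # first node always cluster 0
        firsts = [int(np.flatnonzero(part.labels == c)[0]) for c in range(3)]
        assert firsts == sorted(firsts)

    def test_fiedler_orthogonality_invariant(self):
        A, _ = planted_blocks([15, 15], 0.6, 0.05, seed=9)
        part = spectral_clusters(net_from_adjacency(A), k=2, seed=0)
        assert abs(part.fiedler.sum()) < 1e-8
        assert part.algebraic_connectivity >= 0

    def test_disconnected_error_propagates(self):
        A = np.zeros((6, 6), dtype=int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = A[4, 5] = A[5, 4] = 1
        with pytest.raises(DisconnectedError):
            spectral_clusters(net_from_adjacency(A), k=2, seed=0)


class TestBetweenness:
    def test_path3(self):
        res = betweenness(net_from_adjacency([[0, 1, 0], [1, 0, 1], [0, 1, 0]]))
        np.testing.assert_allclose(res.bc, [0.0, 1.0, 0.0])

    def test_star4(self):
        A = np.zeros((5, 5), dtype=int)
        A[0, 1:] = 1
        A[1:, 0] = 1
        res = betweenness(net_from_adjacency(A))
        assert res.bc[0] == pytest.approx(6.0)  # C(4,2) leaf pairs
        np.testing.assert_allclose(res.bc[1:], 0.0)

    def test_er_graph_matches_oracle(self):
        A = random_graph(25, 0.2, seed=3)
        res = betweenness(net_from_adjacency(A))
        np.testing.assert_allclose(res.bc, brute_force_betweenness(A), atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_property_random_graphs(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n = int(rng.integers(5, 26))
        p = float(rng.uniform(0.1, 0.5))
        A = random_graph(n, p, seed=seed)
        res = betweenness(net_from_adjacency(A))
        np.testing.assert_allclose(res.bc, brute_force_betweenness(A), atol=1e-9)

    def test_tiers(self):
        res = pcn.CentralityResult(bc=np.array([6000.0, 4500.0, 100.0]), tier=[])
        net = net_from_adjacency([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
        out = betweenness(net)
        assert out.tier == ["low", "low", "low"]
        # threshold semantics
        tiers = [
            "high" if v > pcn.BC_HIGH_THRESHOLD else ("medium" if v > pcn.BC_MEDIUM_THRESHOLD else "low")
            for v in res.bc
        ]
        assert tiers == ["high", "medium", "low"]

    def test_disconnected_allowed(self):
        A = np.zeros((4, 4), dtype=int)
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        res = betweenness(net_from_adjacency(A))
        np.testing.assert_allclose(res.bc, 0.0)


class TestInterchainPairing:
    def test_planted_dominant_pair(self):
        bt = gen_bead_trimer(40, {("A", "B"): 20, ("A", "C"): 5, ("B", "C"): 5}, seed=7)
        cal = calpha_coordinates(bt.model)
        net, _ = build_network(cal)
        res = interchain_pairing(net)
        assert res.dominant_pair == ("A", "B")
        assert res.counts == bt.interchain_counts

    def test_symmetric_score_near_one(self):
        bt = gen_bead_trimer(40, {("A", "B"): 12, ("A", "C"): 12, ("B", "C"): 12}, seed=3)
        cal = calpha_coordinates(bt.model)
        net, _ = build_network(cal)
        res = interchain_pairing(net)
        assert res.asymmetry == pytest.approx(1.0, abs=0.35)

    def test_no_interchain_edges_flagged(self):
        cal = [
            ("A", 1, np.zeros(3)),
            ("A", 5, np.array([5.0, 0, 0])),
            ("B", 1, np.array([100.0, 0, 0])),
            ("B", 5, np.array([105.0, 0, 0])),
        ]
        net, _ = build_network(cal)
        res = interchain_pairing(net)
        assert res.dominant_pair is None
        assert all(c == 0 for c in res.counts.values())

    def test_single_chain_error(self):
        net = net_from_adjacency([[0, 1], [1, 0]])
        with pytest.raises(NetworkError):
            interchain_pairing(net)


class TestClusterColorMap:
    def test_majority_blocks_on_bead_trimer(self):
        bt = gen_bead_trimer(40, {("A", "B"): 6, ("A", "C"): 6, ("B", "C"): 6}, seed=17)
        cal = calpha_coordinates(bt.model)
        net, _ = build_network(cal)
        part = spectral_clusters(net, k=3, seed=0)
        df = cluster_color_map(part, net.nodes)
        for chain in "ABC":
            sub = df[df["chain"] == chain]["cluster"]
            modal_frac = sub.value_counts(normalize=True).iloc[0]
            assert modal_frac > 0.8

    def test_constant_column_single_cluster(self):
        part = pcn.ClusterPartition(
            labels=np.zeros(3, dtype=int), fiedler=np.zeros(3), algebraic_connectivity=0.5
        )
        df = cluster_color_map(part, [("A", 1), ("A", 2), ("A", 3)])
        assert (df["cluster"] == 0).all()

    def test_empty_partition_error(self):
        part = pcn.ClusterPartition(
            labels=np.array([], dtype=int), fiedler=np.array([]), algebraic_connectivity=0.0
        )
        with pytest.raises(NetworkError):
            cluster_color_map(part, [])
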