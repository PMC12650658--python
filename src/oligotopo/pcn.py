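"""Residue contact networks: construction, spectral clustering, centrality.

Nodes are residues (Cα positions); an edge joins two residues whose Cα
distance lies strictly inside a (4 Å, 8 Å) window.  Clustering uses the
Laplacian's Fiedler vector (two clusters) or k-means on the 2nd/3rd
eigenvector embedding (three clusters); betweenness centrality is raw
Brandes counts with the high/medium tier thresholds at 5000 and 4000.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

BC_HIGH_THRESHOLD = 5000.0
BC_MEDIUM_THRESHOLD = 4000.0


class NetworkError(ValueError):
    pass


class DisconnectedError(NetworkError):
    """Spectral clustering requested on a disconnected network."""


@dataclass
class ContactNetwork:
    nodes: list[tuple[str, int]]  # (chain_id, residue_number)
    adjacency: np.ndarray
    lower_cut: float = 4.0
    upper_cut: float = 8.0

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency)
        if A.shape != (len(self.nodes), len(self.nodes)):
            raise NetworkError("adjacency shape does not match node count")
        if not np.array_equal(A, A.T):
            raise NetworkError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise NetworkError("adjacency diagonal must be zero")
        self.adjacency = A.astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degree) - self.adjacency

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c, _ in self.nodes:
            seen.setdefault(c, None)
        return list(seen)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(zip(*np.nonzero(np.triu(self.adjacency))))
        return g

    def edge_table(self, coords: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for i, j in zip(*np.nonzero(np.triu(self.adjacency))):
            ci, ri = self.nodes[i]
            cj, rj = self.nodes[j]
            row = {"chain_i": ci, "res_i": ri, "chain_j": cj, "res_j": rj}
            if coords is not None:
                row["distance"] = float(np.linalg.norm(coords[i] - coords[j]))
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class ClusterPartition:
    labels: np.ndarray
    fiedler: np.ndarray
    algebraic_connectivity: float


@dataclass
class CentralityResult:
    bc: np.ndarray
    tier: list[str]


def build_network(
    calphas: list[tuple[str, int, np.ndarray]],
    lower_cut: float = 4.0,
    upper_cut: float = 8.0,
) -> tuple[ContactNetwork, np.ndarray]:
    """Contact network from (chain, residue, Cα position) entries.

    Edges require ``lower_cut < d < upper_cut`` with strict inequalities;
    the 4 Å lower bound naturally excludes sequence-adjacent residues
    (Cα–Cα ≈ 3.8 Å).  Returns the network and the Cα coordinate array
    (row order matches the node order).
    """
    if len(calphas) < 2:
        raise NetworkError("need at least 2 residues")
    if lower_cut >= upper_cut:
        raise NetworkError(f"lower_cut {lower_cut} must be < upper_cut {upper_cut}")
    nodes = [(c, r) for c, r, _ in calphas]
    coords = np.array([p for _, _, p in calphas], dtype=float)
    d = squareform(pdist(coords))
    A = ((d > lower_cut) & (d < upper_cut)).astype(int)
    np.fill_diagonal(A, 0)
    return ContactNetwork(nodes=nodes, adjacency=A, lower_cut=lower_cut, upper_cut=upper_cut), coords


def _check_connected(net: ContactNetwork) -> None:
    g = net.to_networkx()
    if not nx.is_connected(g):
        comps = sorted(nx.connected_components(g), key=len, reverse=True)
        sizes = [len(c) for c in comps]
        raise DisconnectedError(
            f"network is disconnected ({len(comps)} components, sizes {sizes})"
        )


def fiedler_vector(net: ContactNetwork) -> tuple[np.ndarray, float]:
    """Unit-norm eigenvector of L for the second-smallest eigenvalue.

    Sign convention: the first nonzero entry is positive.  Raises
    :class:`DisconnectedError` on disconnected networks, where the zero
    eigenvalue is degenerate.
    """
    _check_connected(net)
    eigvals, eigvecs = np.linalg.eigh(net.laplacian.astype(float))
    v2 = eigvecs[:, 1]
    lam2 = float(eigvals[1])
    nonzero = np.flatnonzero(np.abs(v2) > 1e-12)
    if nonzero.size and v2[nonzero[0]] < 0:
        v2 = -v2
    return v2, lam2


def spectral_clusters(net: ContactNetwork, k: int = 2, seed: int = 0) -> ClusterPartition:
    """Partition the network into k ∈ {2, 3} clusters.

    k = 2: sign of the Fiedler vector (zero entries go with the positive
    side).  k = 3: k-means (50 restarts, fixed seed) on the embedding
    given by the eigenvectors of the 2nd and 3rd smallest Laplacian
    eigenvalues.  Labels are relabelled canonically so cluster ids appear
    in ascending order of their minimum node index.
    """
    if k not in (2, 3):
        raise NetworkError("k must be 2 or 3")
    _check_connected(net)
    eigvals, eigvecs = np.linalg.eigh(net.laplacian.astype(float))
    v2 = eigvecs[:, 1]
    nonzero = np.flatnonzero(np.abs(v2) > 1e-12)
    if nonzero.size and v2[nonzero[0]] < 0:
        v2 = -v2
    lam2 = float(eigvals[1])
    if k == 2:
        labels = np.where(v2 >= 0, 0, 1)
    else:
        from sklearn.cluster import KMeans

        embedding = eigvecs[:, 1:3]
        km = KMeans(n_clusters=3, n_init=50, random_state=seed)
        labels = km.fit_predict(embedding)
    labels = _canonical_labels(labels)
    return ClusterPartition(labels=labels, fiedler=v2, algebraic_connectivity=lam2)


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel so cluster ids ascend with their minimum node index."""
    labels = np.asarray(labels)
    first_seen: dict[int, int] = {}
    for lab in labels:
        if int(lab) not in first_seen:
            first_seen[int(lab)] = len(first_seen)
    return np.array([first_seen[int(lab)] for lab in labels], dtype=int)


def betweenness(net: ContactNetwork) -> CentralityResult:
    """Raw (unnormalized) shortest-path betweenness with Brandes counting.

    Equal-length shortest paths split the pair's unit of mass evenly;
    endpoints are not counted as crossings.  Tiers: high for bc > 5000,
    medium for 4000 < bc <= 5000, low otherwise.  Disconnected networks
    are allowed (computed per component).
    """
    g = net.to_networkx()
    bc_dict = nx.betweenness_centrality(g, normalized=False)
    bc = np.array([bc_dict[i] for i in range(net.n_nodes)], dtype=float)
    tier = [
        "high" if v > BC_HIGH_THRESHOLD else ("medium" if v > BC_MEDIUM_THRESHOLD else "low")
        for v in bc
    ]
    return CentralityResult(bc=bc, tier=tier)


@dataclass
class InterchainPairing:
    counts: dict[tuple[str, str], int]
    dominant_pair: tuple[str, str] | None
    asymmetry: float  # max count / median count (inf if median is 0)


def interchain_pairing(net: ContactNetwork) -> InterchainPairing:
    """Count inter-chain edges per chain pair and locate the dominant pair.

    The asymmetry score is max pair count over the median pair count; a
    network with no inter-chain edges has an undefined dominant pair
    (``None``).
    """
    chains = net.chains
    if len(chains) < 2:
        raise NetworkError("need at least 2 chains for inter-chain analysis")
    chain_of = np.array([c for c, _ in net.nodes])
    counts: dict[tuple[str, str], int] = {
        tuple(sorted(p)): 0 for p in itertools.combinations(chains, 2)
    }
    for i, j in zip(*np.nonzero(np.triu(net.adjacency))):
        ci, cj = chain_of[i], chain_of[j]
        if ci != cj:
            counts[tuple(sorted((ci, cj)))] += 1
    values = np.array(list(counts.values()), dtype=float)
    if values.max() == 0:
        return InterchainPairing(counts=counts, dominant_pair=None, asymmetry=float("nan"))
    dominant = max(counts, key=lambda p: counts[p])
    med = float(np.median(values))
    asym = float(values.max() / med) if med > 0 else float("inf")
    return InterchainPairing(counts=counts, dominant_pair=dominant, asymmetry=asym)


def cluster_color_map(partition: ClusterPartition, nodes: list[tuple[str, int]]) -> pd.DataFrame:
    """Per-residue cluster labels in sequence order, one row per residue."""
    if partition.labels is None or len(partition.labels) == 0:
        raise NetworkError("empty partition")
    if len(partition.labels) != len(nodes):
        raise NetworkError("label count does not match node count")
    df = pd.DataFrame(
        {
            "chain": [c for c, _ in nodes],
            "residue_number": [r for _, r in nodes],
            "cluster": partition.labels,
        }
    )
    return df.sort_values(["chain", "residue_number"], kind="stable").reset_index(drop=True)
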