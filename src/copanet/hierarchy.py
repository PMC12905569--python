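"""Hierarchical organization of a weighted disorder network.

Edge weights are similarities, so clustering uses the distance
d(x, y) = max(e) − e(x, y), with absent edges given similarity 0 (maximal
distance).  Agglomeration is UPGMA (average linkage) with deterministic
lexicographic tie-breaking.  The flat partition is chosen as the dendrogram
cut maximizing the normalized weighted modularity ΔQ_w: observed Q_w minus
its mean over an ensemble of degree- and weight-multiset-preserving
randomizations of the network, evaluated on the same partition.  Partitions
of two networks are compared with ARI and NMI; their raw edge sets with the
Jaccard overlap.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score

from ._kernels import derive_seeds, unipartite_rewire, weighted_null_ensemble
from .errors import NodeSetMismatchError, RigidGraphWarning
from .networks import DisorderNetwork

log = logging.getLogger(__name__)

DEFAULT_N_NULL = 1000
DEFAULT_SWAPS_MULTIPLIER = 10
ATTEMPT_CAP_MULTIPLIER = 100


# ---------------------------------------------------------------------------
# distances and linkage

def distance_matrix(network: DisorderNetwork
                    ) -> tuple[list[str], np.ndarray]:
    """Similarity-to-distance conversion over all node pairs.

    Non-adjacent pairs (including isolated nodes) sit at the maximal distance
    max(e); the maximum-weight pair sits at distance 0.  Weights enter as
    magnitudes, so the matrix is valid for either signed layer.
    """
    if network.n_edges == 0:
        raise ValueError("distance matrix undefined for an edgeless network")
    nodes = network.nodes
    eu, ev, w = network.edge_arrays(nodes)
    emax = float(w.max())
    n = len(nodes)
    dist = np.full((n, n), emax, dtype=float)
    dist[eu, ev] = emax - w
    dist[ev, eu] = emax - w
    np.fill_diagonal(dist, 0.0)
    return nodes, dist


@dataclass
class Partition:
    """Flat clustering of disorder codes; cluster ids are 0..k−1 in order of
    each cluster's lexicographically smallest member."""

    labels: dict[str, int]

    def __post_init__(self):
        self.labels = dict(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    @property
    def nodes(self) -> list[str]:
        return sorted(self.labels)

    def clusters(self) -> list[list[str]]:
        out: dict[int, list[str]] = {}
        for c, k in self.labels.items():
            out.setdefault(k, []).append(c)
        return [sorted(v) for _, v in sorted(out.items())]

    def singletons(self) -> list[str]:
        """Nodes left unclustered (alone in their cluster) at this cut."""
        return sorted(c[0] for c in self.clusters() if len(c) == 1)

    def label_vector(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.labels[c] for c in nodes], dtype=np.int64)

    @classmethod
    def from_clusters(cls, clusters) -> "Partition":
        labels = {c: k for k, block in enumerate(clusters) for c in block}
        return cls._canonical(labels)

    @classmethod
    def _canonical(cls, labels: dict[str, int]) -> "Partition":
        remap: dict[int, int] = {}
        out = {}
        for code in sorted(labels):
            k = labels[code]
            if k not in remap:
                remap[k] = len(remap)
            out[code] = remap[k]
        return cls(out)


@dataclass
class Dendrogram:
    """UPGMA merge tree. ``merges`` follows the scipy linkage convention:
    row t merges cluster ids ``a`` and ``b`` (leaves are 0..n−1, the merge
    creates id n+t) at ``height`` with the resulting ``size``."""

    leaves: list[str]
    merges: np.ndarray  # shape (n-1, 4): a, b, height, size

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def has_inversions(self) -> bool:
        h = self.merges[:, 2]
        return bool(np.any(np.diff(h) < -1e-12))

    def cut(self, height: float) -> Partition:
        """Partition from all merges at height ≤ ``height`` (union-closed, so
        it is well defined even when average linkage produces inversions)."""
        parent = list(range(self.n_leaves))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        members: list[list[int]] = [[i] for i in range(self.n_leaves)]
        reps = {i: i for i in range(self.n_leaves)}  # cluster id -> a leaf
        for t, (a, b, h, _size) in enumerate(self.merges):
            ra, rb = reps[int(a)], reps[int(b)]
            reps[self.n_leaves + t] = ra
            if h <= height + 1e-15:
                pa, pb = find(ra), find(rb)
                if pa != pb:
                    parent[pb] = pa
        groups: dict[int, list[str]] = {}
        for i, code in enumerate(self.leaves):
            groups.setdefault(find(i), []).append(code)
        return Partition._canonical(
            {c: k for k, g in enumerate(groups.values()) for c in g})

    def cut_candidates(self) -> list[float]:
        """All admissible thresholds: −inf (all singletons) plus the sorted
        distinct merge heights."""
        return [-np.inf] + sorted(set(self.merges[:, 2].tolist()))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (leaf height 0)."""
        height_of = {i: 0.0 for i in range(self.n_leaves)}
        node: dict[int, str] = {i: self.leaves[i] for i in range(self.n_leaves)}
        for t, (a, b, h, _size) in enumerate(self.merges):
            a, b = int(a), int(b)
            la = max(h - height_of[a], 0.0)
            lb = max(h - height_of[b], 0.0)
            nid = self.n_leaves + t
            node[nid] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height_of[nid] = h
            del node[a], node[b]
        (root,) = node.values()
        return root + ";"


def average_linkage(nodes: list[str], dist: np.ndarray) -> Dendrogram:
    """UPGMA on a symmetric dissimilarity matrix.

    At every step the pair of clusters with the smallest average inter-cluster
    distance merges; exact ties are broken toward the pair whose smallest
    member codes come first lexicographically, so the tree is deterministic.
    """
    order = np.argsort(np.asarray(nodes, dtype=object))
    leaves = [nodes[i] for i in order]
    n = len(leaves)
    d = {}
    dist = np.asarray(dist, dtype=float)[np.ix_(order, order)]
    active: dict[int, tuple[str, int]] = {
        i: (leaves[i], 1) for i in range(n)}  # id -> (min code, size)
    for i in range(n):
        for j in range(i + 1, n):
            d[(i, j)] = dist[i, j]
    merges = np.zeros((n - 1, 4))
    next_id = n
    for t in range(n - 1):
        best = None
        for (i, j), dij in d.items():
            ri, rj = active[i][0], active[j][0]
            key = (dij, min(ri, rj), max(ri, rj))
            if best is None or key < best[0]:
                best = (key, i, j)
        (_key, i, j) = best
        hij = d.pop((i, j))
        (ri, si), (rj, sj) = active[i], active[j]
        merges[t] = (i, j, hij, si + sj)
        for k in list(active):
            if k in (i, j):
                continue
            dik = d.pop((min(i, k), max(i, k)))
            djk = d.pop((min(j, k), max(j, k)))
            d[(k, next_id)] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[next_id] = (min(ri, rj), si + sj)
        next_id += 1
    dend = Dendrogram(leaves, merges)
    if dend.has_inversions():
        log.info("average-linkage dendrogram contains height inversions")
    return dend


# ---------------------------------------------------------------------------
# weighted modularity and its null

@dataclass
class ModularityResult:
    q_w: float
    expected_q_null: float
    delta_q: float
    n_null: int
    cut_height: float
    n_clusters: int


def _q_from_arrays(eu, ev, w, labels, two_w) -> float:
    within = labels[eu] == labels[ev]
    win2 = 2.0 * w[within].sum()
    strengths = np.zeros(labels.max() + 1)
    np.add.at(strengths, labels[eu], w)
    np.add.at(strengths, labels[ev], w)
    return win2 / two_w - float((strengths ** 2).sum()) / two_w ** 2


def weighted_modularity(network: DisorderNetwork, partition: Partition) -> float:
    """Q_w = (1/2W) Σ_ij [w_ij − s_i s_j / 2W] 1{c_i = c_j}.

    The double sum runs over ordered pairs including i = j, so the trivial
    single-cluster partition scores exactly 0.  Weights enter as magnitudes.
    """
    nodes = network.nodes
    if set(partition.labels) != set(nodes):
        raise NodeSetMismatchError("partition does not cover the network's nodes")
    eu, ev, w = network.edge_arrays(nodes)
    two_w = 2.0 * w.sum()
    if two_w == 0:
        raise ValueError("modularity undefined for zero total weight")
    return _q_from_arrays(eu, ev, w, partition.label_vector(nodes), two_w)


def rewire_weighted(network: DisorderNetwork, n_swaps: int | None = None,
                    seed: int = 0, count: str = "attempts") -> DisorderNetwork:
    """Degree-preserving randomization where each relocated edge keeps its
    weight, so the degree sequence and the weight multiset are both intact."""
    if network.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    nodes = network.nodes
    eu, ev, w = network.edge_arrays(nodes)
    if n_swaps is None:
        n_swaps = DEFAULT_SWAPS_MULTIPLIER * len(eu)
    cap = ATTEMPT_CAP_MULTIPLIER * len(eu)
    cu, cv, cw, succ = unipartite_rewire(eu, ev, w, len(nodes), n_swaps, cap,
                                         int(seed) & 0x7FFFFFFF,
                                         count == "attempts")
    rigid = succ == 0
    if rigid:
        warnings.warn("no legal swap found; network returned unchanged",
                      RigidGraphWarning)
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from((c, dict(network.graph.nodes[c])) for c in nodes)
    for a, b, wt in zip(cu, cv, cw):
        g.add_edge(nodes[a], nodes[b], weight=float(wt))
    return DisorderNetwork(g, sign=network.sign, rigid=rigid)


def null_ensemble(network: DisorderNetwork, n_null: int = DEFAULT_N_NULL,
                  seed: int = 0, swaps_multiplier: int = DEFAULT_SWAPS_MULTIPLIER,
                  count: str = "attempts"):
    """Stacked edge arrays (EU, EV, W) of ``n_null`` independent rewirings,
    each restarted from the observed network with a derived seed."""
    nodes = network.nodes
    eu, ev, w = network.edge_arrays(nodes)
    n_swaps = swaps_multiplier * len(eu)
    cap = ATTEMPT_CAP_MULTIPLIER * len(eu)
    seeds = derive_seeds(seed, n_null)
    out_u, out_v, out_w, succ = weighted_null_ensemble(
        eu, ev, w, len(nodes), n_swaps, cap, seeds, count == "attempts")
    if succ.max() == 0:
        warnings.warn("graph is rigid under degree-preserving swaps; "
                      "null ensemble equals the observed network",
                      RigidGraphWarning)
    return nodes, out_u, out_v, out_w


def _null_qs(out_u, out_v, out_w, labels, two_w) -> np.ndarray:
    n_null = out_u.shape[0]
    lu = labels[out_u]
    lv = labels[out_v]
    win2 = 2.0 * (out_w * (lu == lv)).sum(axis=1)
    k = int(labels.max()) + 1
    strengths = np.zeros((n_null, k))
    rows = np.broadcast_to(np.arange(n_null)[:, None], out_u.shape)
    np.add.at(strengths, (rows, lu), out_w)
    np.add.at(strengths, (rows, lv), out_w)
    return win2 / two_w - (strengths ** 2).sum(axis=1) / two_w ** 2


def normalized_modularity(network: DisorderNetwork, partition: Partition,
                          n_null: int = DEFAULT_N_NULL, seed: int = 0,
                          cut_height: float = np.nan) -> ModularityResult:
    """ΔQ_w = Q_w(G, π) − E[Q_w(G′, π)] over the rewired ensemble, with the
    partition held fixed."""
    q_obs = weighted_modularity(network, partition)
    nodes, out_u, out_v, out_w = null_ensemble(network, n_null, seed)
    eu, ev, w = network.edge_arrays(nodes)
    two_w = 2.0 * w.sum()
    labels = partition.label_vector(nodes)
    qs = _null_qs(out_u, out_v, out_w, labels, two_w)
    expected = float(qs.mean())
    return ModularityResult(q_obs, expected, q_obs - expected, n_null,
                            cut_height, partition.n_clusters)


def optimal_cut(dendrogram: Dendrogram, network: DisorderNetwork,
                n_null: int = DEFAULT_N_NULL, seed: int = 0,
                ensemble: str = "shared"
                ) -> tuple[Partition, ModularityResult]:
    """Dendrogram cut τ* maximizing ΔQ_w over all admissible cuts.

    One null ensemble is drawn once and reused across cuts ("shared",
    default), which keeps the argmax comparison noise-correlated across
    candidates; "per-cut" draws a fresh ensemble per candidate.  Exact ΔQ_w
    ties break toward fewer clusters.
    """
    if sorted(dendrogram.leaves) != network.nodes:
        raise NodeSetMismatchError("dendrogram leaves do not match the network")
    if ensemble not in ("shared", "per-cut"):
        raise ValueError("ensemble must be 'shared' or 'per-cut'")
    nodes = network.nodes
    eu, ev, w = network.edge_arrays(nodes)
    two_w = 2.0 * w.sum()
    if ensemble == "shared":
        _, out_u, out_v, out_w = null_ensemble(network, n_null, seed)
    best: tuple[float, int] | None = None
    best_result: tuple[Partition, ModularityResult] | None = None
    for ci, height in enumerate(dendrogram.cut_candidates()):
        part = dendrogram.cut(height)
        labels = part.label_vector(nodes)
        q_obs = _q_from_arrays(eu, ev, w, labels, two_w)
        if ensemble == "per-cut":
            _, out_u, out_v, out_w = null_ensemble(network, n_null,
                                                   (seed + 7919 * ci))
        qs = _null_qs(out_u, out_v, out_w, labels, two_w)
        delta = q_obs - float(qs.mean())
        key = (delta, -part.n_clusters)
        if best is None or key > best:
            best = key
            best_result = (part, ModularityResult(
                q_obs, float(qs.mean()), delta, n_null, float(height),
                part.n_clusters))
    assert best_result is not None
    return best_result


# ---------------------------------------------------------------------------
# partition and edge-set comparison

@dataclass
class ComparisonResult:
    ari: float
    nmi: float
    edge_jaccard: float
    shared_edge_fraction: tuple[float, float]
    n_shared_edges: int


def compare_partitions(p1: Partition, p2: Partition) -> tuple[float, float]:
    """(ARI, NMI) between two partitions of the same node set.

    ARI uses the permutation-model chance adjustment; NMI normalizes by the
    arithmetic mean of the two entropies.
    """
    if set(p1.labels) != set(p2.labels):
        diff = set(p1.labels) ^ set(p2.labels)
        raise NodeSetMismatchError(f"partitions differ on nodes: {sorted(diff)}")
    nodes = p1.nodes
    a = p1.label_vector(nodes)
    b = p2.label_vector(nodes)
    ari = float(adjusted_rand_score(a, b))
    nmi = float(normalized_mutual_info_score(a, b, average_method="arithmetic"))
    return ari, nmi


def edge_overlap(net1: DisorderNetwork, net2: DisorderNetwork
                 ) -> tuple[float, tuple[float, float]]:
    """Jaccard overlap of the two edge sets on the shared node universe, plus
    the shared fraction relative to each network's own edge count."""
    common = set(net1.graph.nodes) & set(net2.graph.nodes)
    if common != set(net1.graph.nodes) or common != set(net2.graph.nodes):
        log.info("edge_overlap restricted to %d shared nodes", len(common))
    e1 = {e for e in net1.edge_set() if e[0] in common and e[1] in common}
    e2 = {e for e in net2.edge_set() if e[0] in common and e[1] in common}
    if not e1 and not e2:
        raise ValueError("edge overlap undefined: both edge sets empty")
    shared = len(e1 & e2)
    union = len(e1 | e2)
    f1 = shared / len(e1) if e1 else 0.0
    f2 = shared / len(e2) if e2 else 0.0
    return shared / union, (f1, f2)


def compare_networks(net1: DisorderNetwork, p1: Partition,
                     net2: DisorderNetwork, p2: Partition) -> ComparisonResult:
    ari, nmi = compare_partitions(p1, p2)
    jac, fracs = edge_overlap(net1, net2)
    common = set(net1.graph.nodes) & set(net2.graph.nodes)
    e1 = {e for e in net1.edge_set() if e[0] in common and e[1] in common}
    e2 = {e for e in net2.edge_set() if e[0] in common and e[1] in common}
    return ComparisonResult(ari, nmi, jac, fracs, len(e1 & e2))
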