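"""Inference of signed disorder-association networks from coposting.

The association between two disorders is the overlap coefficient of their
user sets, |A ∩ B| / min(|A|, |B|).  Its significance is judged against a
binary bipartite configuration model: the user-disorder graph is repeatedly
randomized by degree-preserving double edge swaps, the overlap is recomputed
on every replicate, and the observed value is converted to a z score against
the replicate mean and standard deviation.  Pairs passing a Bonferroni-
corrected two-sided normal test form the positive (z > 0) and negative
(z < 0) association networks, weighted by observed − expected overlap.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._kernels import (
    bipartite_rewire,
    derive_seeds,
    null_overlap_accumulate,
)
from .errors import DegenerateNullWarning, RigidGraphWarning, UndefinedMetricError
from .networks import DisorderNetwork, UserDisorderGraph

DEFAULT_ALPHA = 0.001
DEFAULT_N_REPS = 10_000
DEFAULT_SWAPS_MULTIPLIER = 10
ATTEMPT_CAP_MULTIPLIER = 100  # per replicate, in units of |E|


@dataclass
class AssociationEdge:
    """Null-model statistics for one disorder pair (a < b lexicographically)."""

    disorder_a: str
    disorder_b: str
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p: float
    sign: str          # "positive" | "negative" | "none"
    weight: float      # observed − null_mean, signed

    def __post_init__(self):
        if self.disorder_a > self.disorder_b:
            raise ValueError("pair must be ordered disorder_a < disorder_b")


def overlap_coefficient(a: set, b: set) -> float:
    """|A ∩ B| / min(|A|, |B|); symmetric, in [0, 1]."""
    if not a or not b:
        raise UndefinedMetricError("overlap coefficient is undefined for an empty set")
    return len(a & b) / min(len(a), len(b))


def observed_overlaps(graph: UserDisorderGraph) -> pd.DataFrame:
    """Overlap coefficient for every disorder pair of the bipartite graph."""
    sizes = graph.disorder_degrees()
    if np.any(sizes == 0):
        empty = [str(graph.disorders[i]) for i in np.nonzero(sizes == 0)[0]]
        raise UndefinedMetricError(
            f"disorders with zero users must be dropped first: {empty}")
    m = graph.membership_matrix()
    counts = (m.T.astype(np.int64) @ m.astype(np.int64))
    codes = [str(d) for d in graph.disorders]
    rows = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            a, b = sorted((codes[i], codes[j]))
            rows.append({
                "disorder_a": a,
                "disorder_b": b,
                "observed": counts[i, j] / min(sizes[i], sizes[j]),
            })
    return pd.DataFrame(rows)


def rewire_bipartite(graph: UserDisorderGraph, n_swaps: int | None = None,
                     seed: int = 0, count: str = "attempts") -> UserDisorderGraph:
    """One degree-preserving randomization of the bipartite graph.

    ``count="attempts"`` (default) runs ``n_swaps`` proposal steps of the lazy
    double-edge-swap chain, whose stationary law is uniform over all simple
    bipartite graphs with the observed degree sequences.  ``count="successful"``
    instead runs until ``n_swaps`` proposals have been accepted (capped at
    ``ATTEMPT_CAP_MULTIPLIER × |E|`` attempts).  If no proposal is accepted the
    input is returned with ``rigid=True``.
    """
    if graph.n_edges < 2:
        raise ValueError("rewiring needs at least 2 edges")
    if count not in ("attempts", "successful"):
        raise ValueError("count must be 'attempts' or 'successful'")
    if n_swaps is None:
        n_swaps = DEFAULT_SWAPS_MULTIPLIER * graph.n_edges
    cap = ATTEMPT_CAP_MULTIPLIER * graph.n_edges
    eu, ed, succ = bipartite_rewire(
        graph.edge_users, graph.edge_disorders, graph.n_users,
        graph.n_disorders, n_swaps, cap, int(seed) & 0x7FFFFFFF,
        count == "attempts")
    rigid = succ == 0
    if rigid:
        warnings.warn("no legal swap found; graph returned unchanged",
                      RigidGraphWarning)
    return UserDisorderGraph(graph.users, graph.disorders, eu, ed, rigid=rigid)


def null_overlap_stats(graph: UserDisorderGraph, n_reps: int = DEFAULT_N_REPS,
                       swaps_multiplier: int = DEFAULT_SWAPS_MULTIPLIER,
                       seed: int = 0, count: str = "attempts") -> pd.DataFrame:
    """Per-pair mean and sample SD of the overlap under the configuration model.

    Each replicate restarts the swap chain from the observed graph with a
    derived seed (seed XOR replicate index), so results are reproducible and
    independent of execution order.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2 for a sample standard deviation")
    sizes = graph.disorder_degrees()
    if np.any(sizes == 0):
        raise UndefinedMetricError("disorders with zero users must be dropped "
                                   "before null sampling")
    n_swaps = swaps_multiplier * graph.n_edges
    cap = ATTEMPT_CAP_MULTIPLIER * graph.n_edges
    seeds = derive_seeds(seed, n_reps)
    sum_o, sum_o2, _succ = null_overlap_accumulate(
        graph.edge_users, graph.edge_disorders, graph.n_users,
        graph.n_disorders, n_swaps, cap, seeds, count == "attempts")
    codes = [str(d) for d in graph.disorders]
    rows = []
    for i in range(len(codes)):
        for j in range(i + 1, len(codes)):
            mean = sum_o[i, j] / n_reps
            # sample (n-1) variance, clipped against tiny negative round-off
            var = max(0.0, (sum_o2[i, j] - n_reps * mean * mean) / (n_reps - 1))
            a, b = sorted((codes[i], codes[j]))
            rows.append({
                "disorder_a": a,
                "disorder_b": b,
                "null_mean": mean,
                "null_sd": np.sqrt(var),
            })
    return pd.DataFrame(rows)


def classify_pair(observed: float, null_mean: float, null_sd: float,
                  n_pairs: int, alpha: float = DEFAULT_ALPHA
                  ) -> tuple[float, float, str]:
    """z score, two-sided normal p, and sign under Bonferroni correction.

    The family-wise level ``alpha`` is split over the ``n_pairs`` tested
    disorder pairs.  A degenerate null (sd = 0) yields sign "none" when the
    observation equals the null mean, and otherwise a warning with p = 0.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    threshold = alpha / n_pairs
    if null_sd == 0:
        if observed == null_mean:
            return 0.0, 1.0, "none"
        warnings.warn("null sd is 0 but observed deviates from the null mean",
                      DegenerateNullWarning)
        z = np.inf if observed > null_mean else -np.inf
        return z, 0.0, "positive" if observed > null_mean else "negative"
    z = (observed - null_mean) / null_sd
    p = 2.0 * stats.norm.sf(abs(z))
    if p >= threshold:
        return z, p, "none"
    return z, p, "positive" if z > 0 else "negative"


def classify_pairs(table: pd.DataFrame, alpha: float = DEFAULT_ALPHA,
                   n_pairs: int | None = None) -> pd.DataFrame:
    """Vectorized classification of a table with observed and null columns."""
    if n_pairs is None:
        n_pairs = len(table)
    out = table.copy()
    zs, ps, signs, weights = [], [], [], []
    for row in table.itertuples(index=False):
        z, p, sign = classify_pair(row.observed, row.null_mean, row.null_sd,
                                   n_pairs, alpha)
        zs.append(z)
        ps.append(p)
        signs.append(sign)
        weights.append(row.observed - row.null_mean)
    out["z"] = zs
    out["p"] = ps
    out["sign"] = signs
    out["weight"] = weights
    return out


def critical_z(alpha: float, n_pairs: int) -> float:
    """|z| above which a pair is significant under the two-sided Bonferroni rule."""
    return float(stats.norm.ppf(1.0 - alpha / n_pairs / 2.0))


def build_networks(classified: pd.DataFrame,
                   categories: dict[str, str] | None = None,
                   n_users: dict[str, int] | None = None
                   ) -> tuple[DisorderNetwork, DisorderNetwork]:
    """Split classified pairs into the positive and negative weighted networks.

    Both networks share the full node set; edge weights are signed
    (observed − null mean), so positive-network weights are > 0 and
    negative-network weights < 0.
    """
    nodes = sorted(set(classified["disorder_a"]) | set(classified["disorder_b"]))
    nets = {}
    for sign in ("positive", "negative"):
        g = nx.Graph()
        for c in nodes:
            g.add_node(c,
                       category=(categories or {}).get(c, ""),
                       n_users=int((n_users or {}).get(c, 0)))
        sub = classified[classified["sign"] == sign]
        for row in sub.itertuples(index=False):
            g.add_edge(row.disorder_a, row.disorder_b,
                       weight=float(row.weight), sign=sign,
                       observed=float(row.observed),
                       null_mean=float(row.null_mean),
                       null_sd=float(row.null_sd),
                       z=float(row.z), p=float(row.p))
        nets[sign] = DisorderNetwork(g, sign=sign)
    return nets["positive"], nets["negative"]


def node_metrics(network: DisorderNetwork,
                 categories: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-node degree, weighted degree (sum of |weight|), and the intra- vs
    inter-category split of each node's edges."""
    g = network.graph
    rows = []
    for node in sorted(g.nodes):
        cat = (categories or {}).get(node, g.nodes[node].get("category"))
        if not cat:
            raise ValueError(f"node {node!r} has no category annotation")
        intra = inter = 0
        wdeg = 0.0
        for nb in g.neighbors(node):
            nb_cat = (categories or {}).get(nb, g.nodes[nb].get("category"))
            if nb_cat == cat:
                intra += 1
            else:
                inter += 1
            wdeg += abs(g.edges[node, nb].get("weight", 1.0))
        rows.append({
            "disorder": node,
            "category": cat,
            "unweighted_degree": intra + inter,
            "weighted_degree": wdeg,
            "intra_category_degree": intra,
            "inter_category_degree": inter,
            "n_users": g.nodes[node].get("n_users", 0),
        })
    return pd.DataFrame(rows)


def category_edge_counts(network: DisorderNetwork,
                         categories: dict[str, str] | None = None
                         ) -> tuple[int, int]:
    """Network totals of (intra-category, inter-category) edges."""
    g = network.graph
    intra = inter = 0
    for a, b in g.edges:
        ca = (categories or {}).get(a, g.nodes[a].get("category"))
        cb = (categories or {}).get(b, g.nodes[b].get("category"))
        if ca == cb:
            intra += 1
        else:
            inter += 1
    return intra, inter


def giant_component(network: DisorderNetwork
                    ) -> tuple[list[list[str]], list[str]]:
    """Connected components (size-descending, ties by smallest member code)
    and the list of isolated nodes."""
    g = network.graph
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps = [c for c in comps if len(c) > 1]
    comps.sort(key=lambda c: (-len(c), c[0]))
    isolates = sorted(n for n in g.nodes if g.degree(n) == 0)
    return comps, isolates
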