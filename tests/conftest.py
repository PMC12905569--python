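import networkx as nx
import numpy as np
import pandas as pd
import pytest

from copanet.networks import DisorderNetwork, UserDisorderGraph


@pytest.fixture
def tiny_bipartite():
    """6 users x 3 disorders; small enough for exhaustive enumeration."""
    m = np.array([
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 1],
        [1, 0, 0],
        [0, 1, 1],
        [1, 0, 1],
    ], dtype=bool)
    return UserDisorderGraph.from_memberships(
        [f"u{i}" for i in range(6)], ["A", "B", "C"], m)


@pytest.fixture
def two_triangle_network():
    """Two unit-weight triangles joined by a single unit bridge."""
    g = nx.Graph()
    edges = [("a1", "a2"), ("a2", "a3"), ("a1", "a3"),
             ("b1", "b2"), ("b2", "b3"), ("b1", "b3"),
             ("a3", "b1")]
    for u, v in edges:
        g.add_edge(u, v, weight=1.0)
    return DisorderNetwork(g)


def make_network(weighted_edges, nodes=None, sign="positive"):
    g = nx.Graph()
    if nodes:
        g.add_nodes_from(nodes)
    for a, b, w in weighted_edges:
        g.add_edge(a, b, weight=w)
    return DisorderNetwork(g, sign=sign)


def make_posts(rows):
    """Post table from (user, community, timestamp[, text]) tuples."""
    recs = []
    for k, row in enumerate(rows):
        user, community, ts = row[:3]
        recs.append({
            "user_id": user,
            "community": community,
            "created_utc": pd.Timestamp(ts, tz="UTC"),
            "post_id": f"p{k:04d}",
            "text": row[3] if len(row) > 3 else None,
        })
    return pd.DataFrame(recs)


def block_similarity_network(rng, **kwargs):
    """Planted-block similarity network (see synth.block_similarity_network)."""
    from copanet.synth import block_similarity_network as _gen

    return _gen(rng, **kwargs)
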