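"""Core containers: the user-disorder bipartite graph and disorder-level networks.

The bipartite graph is kept as flat edge arrays plus node label arrays so the
randomization kernels can operate on integer indices; :class:`DisorderNetwork`
wraps a :class:`networkx.Graph` whose nodes are disorder codes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyGraphError

EDGE_COLUMNS = [
    "disorder_a", "disorder_b", "sign", "observed",
    "null_mean", "null_sd", "z", "p", "weight",
]


@dataclass
class UserDisorderGraph:
    """Simple bipartite graph: users on one side, disorders on the other.

    An edge (u, d) means user ``u`` posted at least once in a community mapped
    to disorder ``d``.  Edges are stored as parallel index arrays into
    ``users`` / ``disorders``; the pair set is unique by construction.
    """

    users: np.ndarray            # str array, shape (n_users,)
    disorders: np.ndarray        # str array, shape (n_disorders,)
    edge_users: np.ndarray       # int64 indices into users
    edge_disorders: np.ndarray   # int64 indices into disorders
    rigid: bool = False          # set when rewiring found no legal swap

    def __post_init__(self) -> None:
        self.edge_users = np.asarray(self.edge_users, dtype=np.int64)
        self.edge_disorders = np.asarray(self.edge_disorders, dtype=np.int64)
        if self.edge_users.shape != self.edge_disorders.shape:
            raise ValueError("edge index arrays must have equal length")
        pairs = set(zip(self.edge_users.tolist(), self.edge_disorders.tolist()))
        if len(pairs) != len(self.edge_users):
            raise ValueError("duplicate (user, disorder) edges are not allowed")

    @property
    def n_users(self) -> int:
        return len(self.users)

    @property
    def n_disorders(self) -> int:
        return len(self.disorders)

    @property
    def n_edges(self) -> int:
        return len(self.edge_users)

    def user_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_users, minlength=self.n_users)

    def disorder_degrees(self) -> np.ndarray:
        return np.bincount(self.edge_disorders, minlength=self.n_disorders)

    def membership_matrix(self) -> np.ndarray:
        """Dense boolean incidence matrix, shape (n_users, n_disorders)."""
        m = np.zeros((self.n_users, self.n_disorders), dtype=bool)
        m[self.edge_users, self.edge_disorders] = True
        return m

    def user_sets(self) -> dict[str, set[str]]:
        """Disorder code -> set of user ids posting under that disorder."""
        out: dict[str, set[str]] = {str(d): set() for d in self.disorders}
        for ui, di in zip(self.edge_users, self.edge_disorders):
            out[str(self.disorders[di])].add(str(self.users[ui]))
        return out

    @classmethod
    def from_memberships(cls, users, disorders, matrix) -> "UserDisorderGraph":
        matrix = np.asarray(matrix, dtype=bool)
        eu, ed = np.nonzero(matrix)
        if len(eu) == 0:
            raise EmptyGraphError("bipartite graph has no edges")
        return cls(np.asarray(users, dtype=object), np.asarray(disorders, dtype=object), eu, ed)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from((f"u::{u}" for u in self.users), bipartite=0)
        g.add_nodes_from((str(d) for d in self.disorders), bipartite=1)
        g.add_edges_from(
            (f"u::{self.users[ui]}", str(self.disorders[di]))
            for ui, di in zip(self.edge_users, self.edge_disorders)
        )
        return g

    def to_edge_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "user_id": self.users[self.edge_users],
            "icd10_l4": self.disorders[self.edge_disorders],
        })


@dataclass
class DisorderNetwork:
    """Undirected weighted network over disorder codes.

    ``sign`` records which layer this is: "positive" / "negative" for the
    significance-filtered coposting layers, "similarity" for the criteria
    overlap network.  Node attributes: ``category``, ``n_users`` (optional).
    Edge attributes: ``weight`` plus, for inferred layers, the null statistics
    (``observed``, ``null_mean``, ``null_sd``, ``z``, ``p``).
    """

    graph: nx.Graph
    sign: str = "positive"
    rigid: bool = False

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return self.n_edges / (n * (n - 1) / 2)

    def edge_arrays(self, nodes: list[str] | None = None):
        """Edges as (u_idx, v_idx, |weight|) index arrays over ``nodes``."""
        nodes = self.nodes if nodes is None else nodes
        index = {c: i for i, c in enumerate(nodes)}
        m = self.n_edges
        eu = np.empty(m, dtype=np.int64)
        ev = np.empty(m, dtype=np.int64)
        w = np.empty(m, dtype=np.float64)
        for k, (a, b, data) in enumerate(sorted(self.graph.edges(data=True))):
            eu[k], ev[k] = index[a], index[b]
            w[k] = abs(data.get("weight", 1.0))
        return eu, ev, w

    def edge_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, b, data in sorted(self.graph.edges(data=True)):
            a, b = sorted((a, b))
            w = data.get("weight", np.nan)
            rows.append({
                "disorder_a": a,
                "disorder_b": b,
                "sign": data.get("sign", self.sign),
                "observed": data.get("observed", np.nan),
                "null_mean": data.get("null_mean", np.nan),
                "null_sd": data.get("null_sd", np.nan),
                "z": data.get("z", np.nan),
                "p": data.get("p", np.nan),
                "weight": w,
                "abs_weight": abs(w),
            })
        return pd.DataFrame(rows, columns=EDGE_COLUMNS + ["abs_weight"])

    def to_adjacency(self, weighted: bool = True) -> pd.DataFrame:
        """Symmetric adjacency matrix; weights or 0/1 presence."""
        nodes = self.nodes
        mat = pd.DataFrame(0.0, index=nodes, columns=nodes)
        for a, b, data in self.graph.edges(data=True):
            val = data.get("weight", 1.0) if weighted else 1.0
            mat.loc[a, b] = mat.loc[b, a] = val
        return mat

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for node in g.nodes:
            g.nodes[node]["degree"] = g.degree(node)
            g.nodes[node]["weighted_degree"] = sum(
                abs(d.get("weight", 1.0)) for _, _, d in g.edges(node, data=True))
        nx.write_graphml(g, path)

    def edge_set(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}
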