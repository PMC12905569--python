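"""Diagnostic-criteria overlap network.

Each disorder is represented as its set of diagnostic criteria; two disorders
are linked whenever they share at least one criterion, with edge weight the
overlap coefficient of the two criteria sets — the same similarity used for
the coposting layer, so the two networks are directly comparable.  No
significance filtering applies: shared criteria are definitional, not
sampled.
"""
from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .assoc import overlap_coefficient
from .errors import EmptyInputError
from .networks import DisorderNetwork

log = logging.getLogger(__name__)


def criteria_sets(table: pd.DataFrame) -> dict[str, set[str]]:
    """Disorder code → set of normalized criterion ids.

    Criterion identity is exact string match after lower-casing and
    whitespace collapsing; duplicate (disorder, criterion) rows collapse.
    """
    if not {"icd10_code", "criterion_id"} <= set(table.columns):
        raise ValueError("criteria table needs icd10_code and criterion_id")
    out: dict[str, set[str]] = {}
    for code, crit in zip(table["icd10_code"], table["criterion_id"]):
        norm = " ".join(str(crit).lower().split())
        out.setdefault(str(code), set()).add(norm)
    return out


def build_criteria_network(table: pd.DataFrame,
                           restrict_to: set[str] | None = None,
                           categories: dict[str, str] | None = None,
                           min_weight: float = 0.0) -> DisorderNetwork:
    """Criteria overlap network restricted to a disorder set.

    Nodes are the restriction set (codes absent from the table are logged and
    dropped); an edge joins every pair with overlap coefficient above
    ``min_weight`` (default: any nonzero overlap).
    """
    sets = criteria_sets(table)
    if restrict_to is None:
        nodes = sorted(sets)
    else:
        restrict_to = {str(c) for c in restrict_to}
        missing = sorted(restrict_to - set(sets))
        if missing:
            log.warning("dropping %d disorders without criteria: %s",
                        len(missing), missing)
        nodes = sorted(restrict_to & set(sets))
    if not nodes:
        raise EmptyInputError("criteria network restriction is empty")
    g = nx.Graph()
    for c in nodes:
        g.add_node(c, category=(categories or {}).get(c, ""),
                   n_criteria=len(sets[c]))
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            w = overlap_coefficient(sets[a], sets[b])
            if w > min_weight:
                g.add_edge(a, b, weight=w, sign="similarity",
                           observed=w)
    return DisorderNetwork(g, sign="similarity")
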