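"""Headline summary numbers in the form they are usually quoted.

These are thin arithmetic helpers so that reported figures (density, mean
activity, multi-community share) are produced by one audited code path
whether they come from a full pipeline run or from published totals.
"""
from __future__ import annotations


def network_density(n_nodes: int, n_edges: int) -> float:
    """|E| / (n(n−1)/2) for a simple undirected graph, to 3 decimals."""
    if n_nodes < 2:
        return 0.0
    return round(n_edges / (n_nodes * (n_nodes - 1) / 2), 3)


def mean_posts_per_user(total_posts: int, total_users: int) -> float:
    """Average contribution per user, to 2 decimals."""
    if total_users <= 0:
        raise ValueError("total_users must be positive")
    return round(total_posts / total_users, 2)


def multi_community_pct(multi_users: int, total_users: int) -> float:
    """Share of users active in 2+ communities, as a percentage, 2 decimals."""
    if total_users <= 0:
        raise ValueError("total_users must be positive")
    return round(100.0 * multi_users / total_users, 2)
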