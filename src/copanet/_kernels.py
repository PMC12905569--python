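"""Numba kernels for degree-preserving edge-swap randomization.

Both kernels implement the "lazy" Markov chain: a step draws an ordered pair
of distinct edges and applies the double swap only when it would neither
duplicate an existing edge nor (unipartite case) create a self-loop.  When
steps are counted as *attempts* the proposal is symmetric and the stationary
distribution is exactly uniform over the degree-matched simple graphs; when
counted as *successes* the chain slightly over-weights graphs with many legal
swaps, so attempts counting is the default upstream.
"""
from __future__ import annotations

import numpy as np
from numba import njit

SEED_MASK = 0x7FFFFFFF


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """Per-replicate seeds: replicate r uses (seed XOR r), masked to 31 bits."""
    return np.array([(int(seed) ^ r) & SEED_MASK for r in range(n)], dtype=np.int64)


@njit(cache=True)
def _bipartite_swap_run(eu, ed, adj, n_swaps, attempt_cap, count_attempts):
    m = eu.shape[0]
    succ = 0
    attempts = 0
    while True:
        if count_attempts:
            if attempts >= n_swaps:
                break
        elif succ >= n_swaps or attempts >= attempt_cap:
            break
        attempts += 1
        a = np.random.randint(m)
        b = np.random.randint(m)
        if a == b:
            continue
        u1, d1 = eu[a], ed[a]
        u2, d2 = eu[b], ed[b]
        if u1 == u2 or d1 == d2:
            continue
        if adj[u1, d2] or adj[u2, d1]:
            continue
        adj[u1, d1] = False
        adj[u2, d2] = False
        adj[u1, d2] = True
        adj[u2, d1] = True
        ed[a] = d2
        ed[b] = d1
        succ += 1
    return succ


@njit(cache=True)
def bipartite_rewire(eu, ed, n_users, n_disorders, n_swaps, attempt_cap, seed,
                     count_attempts):
    """One rewired copy of the bipartite graph; returns (edges_d, n_success)."""
    np.random.seed(seed)
    m = eu.shape[0]
    cu = eu.copy()
    cd = ed.copy()
    adj = np.zeros((n_users, n_disorders), dtype=np.bool_)
    for k in range(m):
        adj[cu[k], cd[k]] = True
    succ = _bipartite_swap_run(cu, cd, adj, n_swaps, attempt_cap, count_attempts)
    return cu, cd, succ


@njit(cache=True)
def null_overlap_accumulate(eu, ed, n_users, n_disorders, n_swaps, attempt_cap,
                            seeds, count_attempts):
    """Accumulate overlap-coefficient sums over the rewired ensemble.

    Returns (sum, sum-of-squares) matrices over disorder pairs (upper
    triangle) and the per-replicate successful-swap counts.
    """
    m = eu.shape[0]
    n_reps = seeds.shape[0]
    sizes = np.zeros(n_disorders, dtype=np.int64)
    for k in range(m):
        sizes[ed[k]] += 1
    sum_o = np.zeros((n_disorders, n_disorders))
    sum_o2 = np.zeros((n_disorders, n_disorders))
    succ_counts = np.zeros(n_reps, dtype=np.int64)
    memb = np.empty(n_disorders, dtype=np.int64)
    for r in range(n_reps):
        np.random.seed(seeds[r])
        cu = eu.copy()
        cd = ed.copy()
        adj = np.zeros((n_users, n_disorders), dtype=np.bool_)
        for k in range(m):
            adj[cu[k], cd[k]] = True
        succ_counts[r] = _bipartite_swap_run(cu, cd, adj, n_swaps, attempt_cap,
                                             count_attempts)
        counts = np.zeros((n_disorders, n_disorders))
        for u in range(n_users):
            cnt = 0
            for d in range(n_disorders):
                if adj[u, d]:
                    memb[cnt] = d
                    cnt += 1
            for i in range(cnt):
                for j in range(i + 1, cnt):
                    counts[memb[i], memb[j]] += 1.0
        for i in range(n_disorders):
            for j in range(i + 1, n_disorders):
                denom = min(sizes[i], sizes[j])
                if denom > 0:
                    o = counts[i, j] / denom
                    sum_o[i, j] += o
                    sum_o2[i, j] += o * o
    return sum_o, sum_o2, succ_counts


@njit(cache=True)
def _unipartite_swap_run(eu, ev, w, adj, n_swaps, attempt_cap, count_attempts):
    m = eu.shape[0]
    succ = 0
    attempts = 0
    while True:
        if count_attempts:
            if attempts >= n_swaps:
                break
        elif succ >= n_swaps or attempts >= attempt_cap:
            break
        attempts += 1
        a = np.random.randint(m)
        b = np.random.randint(m)
        if a == b:
            continue
        u1, v1 = eu[a], ev[a]
        if np.random.randint(2) == 1:
            u1, v1 = v1, u1
        u2, v2 = eu[b], ev[b]
        if np.random.randint(2) == 1:
            u2, v2 = v2, u2
        # propose (u1, v2) and (u2, v1); each relocated edge keeps its weight
        if u1 == v2 or u2 == v1:
            continue
        if adj[u1, v2] or adj[u2, v1]:
            continue
        if (u1 == u2 and v2 == v1) or (u1 == v1):
            continue
        adj[u1, v1] = False
        adj[v1, u1] = False
        adj[u2, v2] = False
        adj[v2, u2] = False
        adj[u1, v2] = True
        adj[v2, u1] = True
        adj[u2, v1] = True
        adj[v1, u2] = True
        eu[a], ev[a] = u1, v2
        eu[b], ev[b] = u2, v1
        succ += 1
    return succ


@njit(cache=True)
def unipartite_rewire(eu, ev, w, n_nodes, n_swaps, attempt_cap, seed,
                      count_attempts):
    """One degree- and weight-multiset-preserving rewired copy."""
    np.random.seed(seed)
    m = eu.shape[0]
    cu = eu.copy()
    cv = ev.copy()
    cw = w.copy()
    adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
    for k in range(m):
        adj[cu[k], cv[k]] = True
        adj[cv[k], cu[k]] = True
    succ = _unipartite_swap_run(cu, cv, cw, adj, n_swaps, attempt_cap,
                                count_attempts)
    return cu, cv, cw, succ


@njit(cache=True)
def weighted_null_ensemble(eu, ev, w, n_nodes, n_swaps, attempt_cap, seeds,
                           count_attempts):
    """Stack of rewired copies: edge index and weight arrays per replicate."""
    m = eu.shape[0]
    n_null = seeds.shape[0]
    out_u = np.empty((n_null, m), dtype=np.int64)
    out_v = np.empty((n_null, m), dtype=np.int64)
    out_w = np.empty((n_null, m), dtype=np.float64)
    succ_counts = np.zeros(n_null, dtype=np.int64)
    for r in range(n_null):
        np.random.seed(seeds[r])
        cu = eu.copy()
        cv = ev.copy()
        cw = w.copy()
        adj = np.zeros((n_nodes, n_nodes), dtype=np.bool_)
        for k in range(m):
            adj[cu[k], cv[k]] = True
            adj[cv[k], cu[k]] = True
        succ_counts[r] = _unipartite_swap_run(cu, cv, cw, adj, n_swaps,
                                              attempt_cap, count_attempts)
        out_u[r] = cu
        out_v[r] = cv
        out_w[r] = cw
    return out_u, out_v, out_w, succ_counts
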