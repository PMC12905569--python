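"""Independent brute-force oracles used to verify the fast implementations.

Everything here is deliberately naive: exhaustive enumeration, double loops,
and direct pair counting.  None of it shares code with the package.
"""
import itertools

import numpy as np


def enumerate_bipartite(row_deg, col_deg):
    """All 0/1 matrices with the given row and column sums."""
    n_cols = len(col_deg)
    per_row = []
    for k in row_deg:
        per_row.append([
            np.array([1 if i in chosen else 0 for i in range(n_cols)])
            for chosen in itertools.combinations(range(n_cols), int(k))
        ])
    out = []
    target = np.asarray(col_deg)
    for combo in itertools.product(*per_row):
        m = np.vstack(combo)
        if np.array_equal(m.sum(axis=0), target):
            out.append(m)
    return out


def exact_overlap_stats(row_deg, col_deg):
    """Exact mean and SD of the pairwise overlap coefficient over the uniform
    ensemble of degree-matched simple bipartite graphs."""
    graphs = enumerate_bipartite(row_deg, col_deg)
    n_cols = len(col_deg)
    values = {(i, j): [] for i in range(n_cols) for j in range(i + 1, n_cols)}
    for m in graphs:
        counts = m.T @ m
        sizes = m.sum(axis=0)
        for (i, j), acc in values.items():
            acc.append(counts[i, j] / min(sizes[i], sizes[j]))
    mean = {p: float(np.mean(v)) for p, v in values.items()}
    sd = {p: float(np.std(v)) for p, v in values.items()}
    return mean, sd, len(graphs)


def naive_weighted_modularity(nodes, edges, labels):
    """Q_w by the explicit double loop over ordered node pairs.

    ``edges`` is {(a, b): weight}; ``labels`` maps node -> cluster id.
    """
    w = {}
    for (a, b), wt in edges.items():
        w[(a, b)] = w[(b, a)] = wt
    strength = {n: sum(w.get((n, m), 0.0) for m in nodes) for n in nodes}
    two_w = sum(strength.values())
    q = 0.0
    for i in nodes:
        for j in nodes:
            if labels[i] == labels[j]:
                q += w.get((i, j), 0.0) - strength[i] * strength[j] / two_w
    return q / two_w


def pair_counting_ari(labels_a, labels_b):
    """ARI from explicit agreement counts over all node pairs."""
    n = len(labels_a)
    a = b = c = d = 0  # together/together, together/apart, apart/together, apart/apart
    for i in range(n):
        for j in range(i + 1, n):
            same_a = labels_a[i] == labels_a[j]
            same_b = labels_b[i] == labels_b[j]
            if same_a and same_b:
                a += 1
            elif same_a:
                b += 1
            elif same_b:
                c += 1
            else:
                d += 1
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    max_index = ((a + b) + (a + c)) / 2
    if max_index == expected:
        return 1.0 if b == 0 and c == 0 else 0.0
    return (a - expected) / (max_index - expected)


def cophenetic_matrix(leaves, merges):
    """Leaf-pair cophenetic heights from a merge list (scipy id convention)."""
    n = len(leaves)
    members = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    for t, (a, b, h, _s) in enumerate(merges):
        ma, mb = members.pop(int(a)), members.pop(int(b))
        for i in ma:
            for j in mb:
                coph[i, j] = coph[j, i] = h
        members[n + t] = ma | mb
    return coph
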