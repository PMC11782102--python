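"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — exhaustive nearest-background
search, Bellman–Ford relaxation, O(n^2) pairwise concordance, textbook
formula evaluation — and shares no code with the library paths it checks.
"""

import numpy as np
from scipy import stats


def brute_force_interior_distance(values, spacing):
    """Nearest-background search by exhaustive enumeration."""
    values = np.asarray(values)
    bg = np.argwhere(values == 0) * np.asarray(spacing)
    out = np.zeros(values.shape)
    for v in np.argwhere(values == 1):
        out[tuple(v)] = np.min(np.linalg.norm(bg - v * np.asarray(spacing), axis=1))
    return out


def bellman_ford_cost(values, spacing, distance, src, dst, p=2.0):
    """Shortest-path cost on the 26-connected voxel graph by relaxation."""
    nodes = [tuple(v) for v in np.argwhere(np.asarray(values) == 1)]
    index = {v: i for i, v in enumerate(nodes)}
    edges = []
    for u in nodes:
        for off in np.ndindex(3, 3, 3):
            dvec = np.array(off) - 1
            if not dvec.any():
                continue
            v = tuple(np.array(u) + dvec)
            if v in index:
                step = np.linalg.norm(dvec * np.asarray(spacing))
                edges.append((index[u], index[v],
                              step / (1.0 + distance[v]) ** p))
    dist = np.full(len(nodes), np.inf)
    dist[index[tuple(src)]] = 0.0
    for _ in range(len(nodes) - 1):
        changed = False
        for a, b, w in edges:
            if dist[a] + w < dist[b]:
                dist[b] = dist[a] + w
                changed = True
        if not changed:
            break
    return dist[index[tuple(dst)]]


def concordance_oracle(scores, labels):
    """AUROC as O(n^2) pairwise concordance with half-credit ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def welch_formula_oracle(a, b):
    """Welch statistic, Welch-Satterthwaite df, two-sided p from the
    textbook formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def percentile_interpolation_oracle(values, level):
    """Closest-ranks linear-interpolation percentile by hand."""
    v = np.sort(np.asarray(values, float))
    rank = (level / 100.0) * (len(v) - 1)
    lo, hi = int(np.floor(rank)), int(np.ceil(rank))
    return v[lo] + (rank - lo) * (v[hi] - v[lo])
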