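"""Independent oracles used by the test suite.

These deliberately avoid the code paths they validate: the MST oracle
enumerates every labelled spanning tree via the Prufer-sequence bijection
instead of running a greedy algorithm, and the small-n variant checks all
edge subsets directly.
"""

import itertools

import numpy as np
from numba import njit


@njit(cache=True)
def mst_weight_exhaustive(W):
    """Minimum spanning-tree weight of a complete graph by exhaustive
    enumeration of all n^(n-2) Prufer sequences (n <= 8 is practical)."""
    n = W.shape[0]
    m = n - 2
    total = 1
    for _ in range(m):
        total *= n
    best = 1e300
    seq = np.zeros(m, dtype=np.int64)
    deg = np.zeros(n, dtype=np.int64)
    for s in range(total):
        t = s
        for i in range(m):
            seq[i] = t % n
            t //= n
        for i in range(n):
            deg[i] = 1
        for i in range(m):
            deg[seq[i]] += 1
        w = 0.0
        for i in range(m):
            v = seq[i]
            u = -1
            for cand in range(n):
                if deg[cand] == 1:
                    u = cand
                    break
            w += W[u, v]
            deg[u] -= 1
            deg[v] -= 1
        u = -1
        v = -1
        for cand in range(n):
            if deg[cand] == 1:
                if u < 0:
                    u = cand
                else:
                    v = cand
        w += W[u, v]
        if w < best:
            best = w
    return best


def mst_weight_subsets(points):
    """Brute-force MST weight by scanning all (n-1)-edge subsets (n <= 6)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    edges = list(itertools.combinations(range(n), 2))
    weights = {e: float(np.linalg.norm(points[e[0]] - points[e[1]])) for e in edges}
    best = np.inf
    for subset in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        ok = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(weights[e] for e in subset))
    return best


def circumcircle_contains(tri_pts, query):
    """True if ``query`` lies strictly inside the circumcircle of the
    triangle (orientation-corrected determinant test)."""
    a, b, c = (np.asarray(p, dtype=float) for p in tri_pts)
    q = np.asarray(query, dtype=float)
    mat = np.array(
        [
            [a[0] - q[0], a[1] - q[1], (a[0] - q[0]) ** 2 + (a[1] - q[1]) ** 2],
            [b[0] - q[0], b[1] - q[1], (b[0] - q[0]) ** 2 + (b[1] - q[1]) ** 2],
            [c[0] - q[0], c[1] - q[1], (c[0] - q[0]) ** 2 + (c[1] - q[1]) ** 2],
        ]
    )
    orient = np.sign(
        (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
    )
    return orient * np.linalg.det(mat) > 1e-9
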