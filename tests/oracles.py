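"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: decompositions are
found by exhaustive set-partition search over tubule edges, and the EMD
by solving the transport linear program directly.
"""

import itertools

import numpy as np
from scipy.optimize import linprog


def set_partitions(items):
    """All set partitions of a list (exponential; small inputs only)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def _block_is_simple_path(block, edges):
    """True if the edge block forms a simple path in the host graph."""
    deg = {}
    for k in block:
        u, v = edges[k][0], edges[k][1]
        deg[u] = deg.get(u, 0) + 1
        deg[v] = deg.get(v, 0) + 1
    if any(d > 2 for d in deg.values()):
        return False
    # connectivity + acyclicity: a path of b edges spans b+1 nodes
    if len(deg) != len(block) + 1:
        return False
    # connectivity check by walking from a degree-1 node
    start = next(n for n, d in deg.items() if d == 1)
    seen_edges, cur, prev_edge = set(), start, None
    while True:
        nxt = [k for k in block if k not in seen_edges and cur in (edges[k][0], edges[k][1])]
        if not nxt:
            break
        k = nxt[0]
        seen_edges.add(k)
        u, v = edges[k][0], edges[k][1]
        cur = v if cur == u else u
    return len(seen_edges) == len(block)


def brute_force_decompositions(top):
    """All edge partitions of an acyclic topology multigraph into simple
    paths, as a set of frozensets of path-length tuples.

    Each partition is represented by the sorted tuple of its path
    lengths (fixtures use distinct power-of-two arm lengths so a length
    sum identifies its edge set uniquely).
    """
    edges = {k: (u, v, d["length_um"])
             for k, (u, v, d) in enumerate((u, v, d) for u, v, d in top.edges(data=True))}
    results = []
    for part in set_partitions(list(edges)):
        if all(_block_is_simple_path(b, edges) for b in part):
            lengths = tuple(sorted(round(sum(edges[k][2] for k in b), 9) for b in part))
            results.append(lengths)
    return sorted(results)


def emd_lp(masses1, masses2, midpoints):
    """Min-cost transport between two histograms, by linear program."""
    m1 = np.asarray(masses1, dtype=float)
    m2 = np.asarray(masses2, dtype=float)
    n = len(m1)
    cost = np.abs(midpoints[:, None] - midpoints[None, :]).ravel()
    a_eq = []
    for i in range(n):  # row sums = m1
        row = np.zeros((n, n))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(n):  # col sums = m2
        col = np.zeros((n, n))
        col[:, j] = 1
        a_eq.append(col.ravel())
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=np.r_[m1, m2],
                  bounds=(0, None), method="highs")
    assert res.success
    return res.fun
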