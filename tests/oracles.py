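"""Independent brute-force reference implementations used only by the tests.

Every function here is a deliberately naive pure-enumeration computation,
sharing no code path with the package, so agreement is evidence of
correctness rather than of shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# ---------------------------------------------------------------------------
# Graph-metric oracles (adjacency = symmetric boolean matrix, zero diagonal)
# ---------------------------------------------------------------------------

def pairs_shortest_hops(adj: np.ndarray) -> np.ndarray:
    """Floyd–Warshall hop counts; inf where unreachable."""
    n = len(adj)
    d = np.where(adj, 1.0, math.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    return d


def degree_oracle(adj: np.ndarray, i: int) -> int:
    return sum(1 for j in range(len(adj)) if j != i and adj[i][j])


def density_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    edges = sum(
        1 for i in range(n) for j in range(i + 1, n) if adj[i][j]
    )
    return edges / (n * (n - 1) / 2)


def closeness_oracle(adj: np.ndarray, i: int) -> float:
    d = pairs_shortest_hops(adj)[i]
    reach = [d[j] for j in range(len(adj)) if j != i and math.isfinite(d[j])]
    if not reach:
        return math.nan
    return len(reach) / sum(reach)


def apl_oracle(adj: np.ndarray) -> float:
    d = pairs_shortest_hops(adj)
    vals = [
        d[i][j]
        for i in range(len(adj))
        for j in range(i + 1, len(adj))
        if math.isfinite(d[i][j])
    ]
    if not vals:
        return math.nan
    return sum(vals) / len(vals)


def _is_connected(adj: np.ndarray, nodes: tuple[int, ...]) -> bool:
    nodes = list(nodes)
    seen = {nodes[0]}
    frontier = [nodes[0]]
    node_set = set(nodes)
    while frontier:
        u = frontier.pop()
        for v in node_set:
            if v not in seen and adj[u][v]:
                seen.add(v)
                frontier.append(v)
    return seen == node_set


def vertex_connectivity_oracle(adj: np.ndarray, nodes: tuple[int, ...]) -> int:
    """Minimum number of vertex removals disconnecting the induced subgraph
    (n−1 for a complete subgraph), by exhaustive removal-set enumeration."""
    nodes = tuple(nodes)
    n = len(nodes)
    if n < 2:
        return 0
    if not _is_connected(adj, nodes):
        return 0
    complete = all(adj[a][b] for a, b in itertools.combinations(nodes, 2))
    if complete:
        return n - 1
    for k in range(1, n - 1):
        for removal in itertools.combinations(nodes, k):
            rest = tuple(v for v in nodes if v not in removal)
            if len(rest) >= 2 and not _is_connected(adj, rest):
                return k
    return n - 1


def embeddedness_oracle(adj: np.ndarray, i: int) -> int:
    """Max vertex connectivity over all connected vertex subsets containing i."""
    n = len(adj)
    best = 0
    others = [v for v in range(n) if v != i]
    for r in range(1, n):
        for combo in itertools.combinations(others, r):
            nodes = (i,) + combo
            if not _is_connected(adj, nodes):
                continue
            k = vertex_connectivity_oracle(adj, nodes)
            if k > best:
                best = k
    return best


def cut_points_oracle(adj: np.ndarray) -> int:
    """Edges whose removal splits their component into parts of size >= 2."""
    n = len(adj)
    count = 0
    for i in range(n):
        for j in range(i + 1, n):
            if not adj[i][j]:
                continue
            mod = adj.copy()
            mod[i][j] = mod[j][i] = False
            comp = _component_of(adj, i)
            before = len(comp)
            comp_i = _component_of(mod, i)
            comp_j = _component_of(mod, j)
            if comp_i != comp_j and len(comp_i) >= 2 and (before - len(comp_i)) >= 2:
                count += 1
    return count


def _component_of(adj: np.ndarray, start: int) -> frozenset:
    seen = {start}
    frontier = [start]
    while frontier:
        u = frontier.pop()
        for v in range(len(adj)):
            if v not in seen and adj[u][v]:
                seen.add(v)
                frontier.append(v)
    return frozenset(seen)


def local_clustering_oracle(adj: np.ndarray, i: int) -> float:
    partners = [j for j in range(len(adj)) if j != i and adj[i][j]]
    k = len(partners)
    if k < 2:
        return math.nan
    closed = sum(
        1 for a, b in itertools.combinations(partners, 2) if adj[a][b]
    )
    return closed / (k * (k - 1) / 2)


def transitivity_oracle(adj: np.ndarray) -> float:
    n = len(adj)
    triangles = sum(
        1
        for a, b, c in itertools.combinations(range(n), 3)
        if adj[a][b] and adj[b][c] and adj[a][c]
    )
    triples = sum(
        1
        for center in range(n)
        for a, b in itertools.combinations(
            [j for j in range(n) if j != center and adj[center][j]], 2
        )
    )
    if triples == 0:
        return math.nan
    return 3 * triangles / triples


# ---------------------------------------------------------------------------
# Set partitions and exhaustive map-equation minimization
# ---------------------------------------------------------------------------

def set_partitions(n: int):
    """All partitions of range(n) in restricted-growth label form."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(k + 1):
            labels[i] = lab
            yield from rec(i + 1, k + 1 if lab == k else k)

    yield from rec(0, 0)


def exhaustive_min_L(w: np.ndarray, L_fn) -> tuple[np.ndarray, float]:
    """Global minimum of the description length over all partitions."""
    best, best_L = None, math.inf
    for labels in set_partitions(w.shape[0]):
        L = L_fn(w, labels)
        if L < best_L - 1e-12:
            best, best_L = labels.copy(), L
    return best, best_L


# ---------------------------------------------------------------------------
# Benjamini–Hochberg step-up (hand computation)
# ---------------------------------------------------------------------------

def bh_stepup(pvalues) -> np.ndarray:
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adjusted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


# ---------------------------------------------------------------------------
# Simple-ratio index by direct period counting
# ---------------------------------------------------------------------------

def sri_oracle(observations, a: str, b: str) -> float | None:
    """observations: iterable of (individual, day, location) tuples; period =
    (day, location); co-located = both recorded in the same period."""
    per_a = {(d, l) for ind, d, l in observations if ind == a}
    per_b = {(d, l) for ind, d, l in observations if ind == b}
    if not per_a and not per_b:
        return None
    x = len(per_a & per_b)
    denom = len(per_a | per_b)
    return x / denom if denom else None
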