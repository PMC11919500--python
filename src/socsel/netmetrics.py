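"""Per-group interaction networks and the four analogous trait pairs.

Each social group in each year gets a directed, weighted interaction network
(edge weight = count of affiliative interactions initiated by row toward
column).  From it we compute four pairs of analogous individual/group social
network measures:

==============  =======================  ===========================
social trait    individual measure       group measure
==============  =======================  ===========================
connectivity    degree                   density
closeness       closeness                (inverse) average path length
breakability    embeddedness             (inverse) cut points, size-std.
clustering      local clustering coeff.  transitivity
==============  =======================  ===========================

All measures except the weighted construction itself operate on the
undirected, binarized simplification of the matrix: they are defined in terms
of the presence of social relationships, not interaction rates.  Sign flips
that make "larger = more social" for average path length and cut points are
applied downstream, after standardization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .grouping import GroupPartition
from .records import FitnessRecord, IndividualYear, InteractionRecord

TRAIT_PAIRS = (
    ("degree", "density"),
    ("closeness", "avg_path_length"),
    ("embeddedness", "cut_points_std"),
    ("local_clustering", "transitivity"),
)
INDIVIDUAL_TRAITS = tuple(p[0] for p in TRAIT_PAIRS)
GROUP_TRAITS = tuple(p[1] for p in TRAIT_PAIRS)


@dataclass
class InteractionNetwork:
    """Directed weighted interaction matrix of one group-year."""

    year: int
    group_index: int
    nodes: tuple[str, ...]
    weights: np.ndarray  # integer counts, zero diagonal

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        n = len(self.nodes)
        if n < 2:
            raise ValueError("an interaction network needs at least 2 members")
        if self.weights.shape != (n, n):
            raise ValueError("weight matrix shape does not match node list")
        if (self.weights < 0).any() or np.diag(self.weights).any():
            raise ValueError("weights must be non-negative with zero diagonal")

    @property
    def size(self) -> int:
        return len(self.nodes)

    def index(self, id: str) -> int:
        try:
            return self.nodes.index(id)
        except ValueError:
            raise KeyError(f"{id!r} is not a member of this network") from None

    def undirected_adjacency(self) -> np.ndarray:
        """Binarized symmetric simplification: a relationship exists if any
        interaction occurred in either direction."""
        return (self.weights + self.weights.T) > 0

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        rows, cols = np.nonzero(self.weights)
        for i, j in zip(rows, cols):
            g.add_edge(self.nodes[i], self.nodes[j], weight=int(self.weights[i, j]))
        return g


def build_network(
    interactions: Sequence[InteractionRecord],
    members: Iterable[str],
    year: int = 0,
    group_index: int = 0,
) -> InteractionNetwork:
    """Count directed affiliative interactions among ``members`` only."""
    nodes = tuple(sorted(set(members)))
    if len(nodes) < 2:
        raise ValueError("an interaction network needs at least 2 members")
    idx = {v: i for i, v in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)), dtype=int)
    for rec in interactions:
        i = idx.get(rec.initiator)
        j = idx.get(rec.recipient)
        if i is None or j is None:
            continue
        w[i, j] += 1
    return InteractionNetwork(year=year, group_index=group_index, nodes=nodes, weights=w)


# ---------------------------------------------------------------------------
# Individual measures
# ---------------------------------------------------------------------------

def degree(net: InteractionNetwork, id: str) -> int:
    """Number of distinct social partners (A→B and B→A are one relationship)."""
    i = net.index(id)
    return int(net.undirected_adjacency()[i].sum())


def _hop_distances(adj: np.ndarray, source: int) -> np.ndarray:
    """BFS hop counts from ``source``; unreachable -> -1."""
    n = adj.shape[0]
    dist = np.full(n, -1)
    dist[source] = 0
    frontier = [source]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for u in frontier:
            for v in np.flatnonzero(adj[u]):
                if dist[v] < 0:
                    dist[v] = d
                    nxt.append(v)
        frontier = nxt
    return dist


def closeness(net: InteractionNetwork, id: str) -> float:
    """Reachable-set closeness: r / Σ d(id, j) over the r reachable others.

    Hop counts on the undirected simplification; disconnected targets are
    excluded rather than given infinite distance, and the sum is scaled by the
    reachable-set size so values are comparable across group sizes.
    NA for a within-group isolate.
    """
    i = net.index(id)
    dist = _hop_distances(net.undirected_adjacency(), i)
    reach = dist > 0
    if not reach.any():
        return math.nan
    return float(reach.sum() / dist[reach].sum())


def k_component_membership(net: InteractionNetwork) -> dict[str, int]:
    """Each node's structural-cohesion level: the largest k for which the
    node belongs to some k-vertex-connected subgroup.  Isolates get 0.

    Computed by recursive cohesive blocking with the separating cut-set kept
    on both sides: a k-connected subgroup cannot be split by fewer than k
    removals, so it survives intact inside one component-plus-cutset of any
    minimum cut — which makes the recursion exhaustive, not heuristic (the
    usual one-sided variants can miss the deepest blocks).  Exact for all
    group sizes; visited subsets are memoized.
    """
    adj = net.undirected_adjacency()
    g = nx.Graph()
    g.add_nodes_from(range(net.size))
    rows, cols = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    best = {i: 0 for i in range(net.size)}
    seen: set[frozenset] = set()

    def solve(nodes: frozenset) -> None:
        if len(nodes) < 2 or nodes in seen:
            return
        seen.add(nodes)
        sub = g.subgraph(nodes)
        comps = list(nx.connected_components(sub))
        if len(comps) > 1:
            for comp in comps:
                solve(frozenset(comp))
            return
        if len(nodes) == 2:
            for v in nodes:
                best[v] = max(best[v], 1)
            return
        k = nx.node_connectivity(sub)
        for v in nodes:
            best[v] = max(best[v], k)
        if len(nodes) == k + 1:  # complete: no deeper block exists
            return
        cut = nx.minimum_node_cut(sub)
        for comp in nx.connected_components(g.subgraph(set(nodes) - cut)):
            solve(frozenset(comp) | cut)

    solve(frozenset(range(net.size)))
    return {net.nodes[i]: v for i, v in best.items()}


def embeddedness(net: InteractionNetwork, id: str) -> int:
    """Connectedness within the individual's cluster and group: the deepest
    cohesive (k-vertex-connected) subgroup containing it.  0 for isolates."""
    net.index(id)  # membership check
    return k_component_membership(net)[id]


def local_clustering(net: InteractionNetwork, id: str) -> float:
    """Fraction of the individual's partner pairs that are themselves
    connected; NA when the individual has fewer than 2 partners."""
    adj = net.undirected_adjacency()
    i = net.index(id)
    partners = np.flatnonzero(adj[i])
    k = len(partners)
    if k < 2:
        return math.nan
    sub = adj[np.ix_(partners, partners)]
    return float(sub.sum() / (k * (k - 1)))


# ---------------------------------------------------------------------------
# Group measures
# ---------------------------------------------------------------------------

def density(net: InteractionNetwork) -> float:
    """Observed undirected relationships / possible (n choose 2)."""
    adj = net.undirected_adjacency()
    n = net.size
    return float(adj.sum() / (n * (n - 1)))


def average_path_length(net: InteractionNetwork) -> float:
    """Mean hop distance over all reachable unordered pairs; NA if none."""
    adj = net.undirected_adjacency()
    n = net.size
    total = 0
    pairs = 0
    for i in range(n):
        dist = _hop_distances(adj, i)
        reach = np.flatnonzero(dist > 0)
        reach = reach[reach > i]  # unordered pairs once
        total += int(dist[reach].sum())
        pairs += len(reach)
    if pairs == 0:
        return math.nan
    return float(total / pairs)


def cut_points(net: InteractionNetwork, mode: str = "edge") -> int:
    """Relationships (or, in ``vertex`` mode, individuals) whose loss splits
    their component into two or more parts of at least two individuals each."""
    adj = net.undirected_adjacency()
    g = nx.Graph()
    g.add_nodes_from(range(net.size))
    rows, cols = np.nonzero(np.triu(adj, 1))
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    count = 0
    if mode == "edge":
        for u, v in nx.bridges(g):
            comp = nx.node_connected_component(g, u)
            h = g.subgraph(comp).copy()
            h.remove_edge(u, v)
            sizes = [len(c) for c in nx.connected_components(h)]
            if len(sizes) >= 2 and sorted(sizes)[-2] >= 2:
                count += 1
    elif mode == "vertex":
        for v in nx.articulation_points(g):
            comp = nx.node_connected_component(g, v)
            h = g.subgraph(comp - {v})
            sizes = [len(c) for c in nx.connected_components(h)]
            if sum(s >= 2 for s in sizes) >= 2:
                count += 1
    else:
        raise ValueError(f"unknown cutpoints mode {mode!r}")
    return count


def cut_points_std(net: InteractionNetwork, mode: str = "edge") -> float:
    """Cut points standardized by social group size (network node count)."""
    return cut_points(net, mode=mode) / net.size


def transitivity(net: InteractionNetwork) -> float:
    """Global transitivity: 3 × triangles / connected triples; NA if no
    connected triples exist."""
    adj = net.undirected_adjacency().astype(int)
    deg = adj.sum(axis=1)
    triples = int((deg * (deg - 1) // 2).sum())
    if triples == 0:
        return math.nan
    triangles = int(np.trace(adj @ adj @ adj)) // 6
    return float(3 * triangles / triples)


# ---------------------------------------------------------------------------
# Trait-table assembly
# ---------------------------------------------------------------------------

def network_traits(net: InteractionNetwork, cutpoints_mode: str = "edge") -> dict:
    """The four group measures of one network (shared by all its members)."""
    return {
        "density": density(net),
        "avg_path_length": average_path_length(net),
        "cut_points_std": cut_points_std(net, mode=cutpoints_mode),
        "transitivity": transitivity(net),
        "group_size": net.size,
    }


def individual_traits(
    net: InteractionNetwork, id: str, _embeddedness: dict | None = None
) -> dict:
    emb = (_embeddedness or k_component_membership(net))[id]
    return {
        "degree": degree(net, id),
        "closeness": closeness(net, id),
        "embeddedness": emb,
        "local_clustering": local_clustering(net, id),
    }


def compute_trait_table(
    partition: GroupPartition,
    networks: Sequence[InteractionNetwork],
    meta: Iterable[IndividualYear],
    fitness: Iterable[FitnessRecord] | None = None,
    cutpoints_mode: str = "edge",
) -> tuple[pd.DataFrame, list[str]]:
    """One row per individual-year from the individual's PRIMARY group.

    Both the individual and the group measures of a row come from the primary
    group's network (which includes augmented adult males as nodes), so an
    augmented male's own traits never reflect his secondary groups.
    Individuals without a primary group (isolates) are excluded and returned
    in the second element.
    """
    by_group = {net.group_index: net for net in networks}
    meta_by_id = {m.id: m for m in meta if m.year == partition.year}
    fit_by_id = {}
    if fitness is not None:
        fit_by_id = {f.id: f for f in fitness if f.year == partition.year}
    group_cache = {
        gi: network_traits(net, cutpoints_mode) for gi, net in by_group.items()
    }
    emb_cache = {
        gi: k_component_membership(net) for gi, net in by_group.items()
    }
    rows = []
    excluded: list[str] = []
    for ind in sorted(meta_by_id):
        gi = partition.primary_group.get(ind)
        if gi is None:
            excluded.append(ind)
            continue
        net = by_group[gi]
        m = meta_by_id[ind]
        row = {
            "id": ind,
            "year": partition.year,
            "group": gi,
            "sex": m.sex,
            "age_class": m.age_class,
            "colony": m.colony,
            "elevation": m.elevation,
            "june_mass": m.june_mass,
            "august_mass": m.august_mass,
        }
        row.update(individual_traits(net, ind, emb_cache[gi]))
        row.update(group_cache[gi])
        f = fit_by_id.get(ind)
        row.update(
            {
                "summer_survival": f.summer_survival if f else None,
                "hibernation_survival": f.hibernation_survival if f else None,
                "weaned": f.weaned if f else None,
                "n_weaned": f.n_weaned if f else None,
            }
        )
        rows.append(row)
    table = pd.DataFrame(rows)
    return table, excluded
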