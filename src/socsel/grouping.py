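"""Social-group delineation from raw field records.

The stage runs in four steps, mirroring how the field protocol treats the
data:

1. :func:`filter_interactions` — keep affiliative interactions between known,
   resident (≥ 5 annual observations) adults/yearlings in the spring season
   (April–June by default), with a per-rule removal report.
2. :func:`simple_ratio_index` — pairwise association strength from co-location
   sampling: the fraction of sampling periods in which two individuals were
   together, out of periods in which either was observed.  A sampling period
   is one calendar day at one location by default.
3. :func:`detect_groups` — two-level map-equation community detection on the
   association network.  The objective is the description length of a random
   walk on the undirected weighted network; modules are social groups.
4. :func:`augment_males` — adult males gain (secondary) membership in every
   group containing at least one of their interaction partners; their primary
   assignment, used for trait and fitness attribution, never changes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import (
    ColocationRecord,
    IndividualYear,
    InteractionRecord,
    month_of,
)

DEFAULT_SEASON_MONTHS = (4, 5, 6)
DEFAULT_MIN_OBSERVATIONS = 5


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-rule removal counts, in application order."""

    total_in: int
    removed: list[tuple[str, int]] = field(default_factory=list)
    retained: int = 0

    def removed_by(self, rule: str) -> int:
        return dict(self.removed).get(rule, 0)

    @property
    def total_removed(self) -> int:
        return sum(n for _, n in self.removed)


def filter_interactions(
    records: Sequence[InteractionRecord],
    meta: Iterable[IndividualYear],
    year: int,
    *,
    season_months: Sequence[int] = DEFAULT_SEASON_MONTHS,
    min_annual_observations: int = DEFAULT_MIN_OBSERVATIONS,
) -> tuple[list[InteractionRecord], FilterReport]:
    """Apply the interaction-inclusion rules for one year.

    Rule order: behaviour class (affiliative only) → identity (both
    participants known) → age class (both participants adults or yearlings
    present in the year's metadata) → season window → transient rule (both
    participants observed or trapped at least ``min_annual_observations``
    times that year, counted on raw annual effort, not post-filter counts).
    """
    meta_by_id = {m.id: m for m in meta if m.year == year}
    report = FilterReport(total_in=len(records))
    kept = list(records)

    def apply(rule: str, keep) -> None:
        nonlocal kept
        before = len(kept)
        kept = [r for r in kept if keep(r)]
        report.removed.append((rule, before - len(kept)))

    apply("behaviour", lambda r: r.behaviour == "affiliative")
    apply("identity", lambda r: not r.any_unknown)
    apply(
        "age_class",
        lambda r: r.initiator in meta_by_id and r.recipient in meta_by_id,
    )
    apply("season", lambda r: month_of(r.date) in set(season_months))
    apply(
        "min_observations",
        lambda r: (
            meta_by_id[r.initiator].n_observations >= min_annual_observations
            and meta_by_id[r.recipient].n_observations >= min_annual_observations
        ),
    )
    report.retained = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Simple-ratio association index
# ---------------------------------------------------------------------------

def _period_locations(
    colocations: Iterable[ColocationRecord], individual: str, sampling: str
) -> dict:
    """Map sampling-period key -> set of locations the individual used."""
    out: dict = {}
    for rec in colocations:
        if rec.individual != individual:
            continue
        if sampling == "day_location":
            key = (rec.date, rec.location)
        elif sampling == "day":
            key = rec.date
        else:
            raise ValueError(f"unknown sampling period {sampling!r}")
        out.setdefault(key, set()).add(rec.location)
    return out


def simple_ratio_index(
    colocations: Iterable[ColocationRecord],
    a: str,
    b: str,
    sampling: str = "day_location",
) -> float | None:
    """Simple-ratio association index x / (x + y_a + y_b + y_ab).

    x — periods in which a and b were co-located (shared a location);
    y_a / y_b — periods in which only a / only b was observed;
    y_ab — periods in which both were observed but not co-located
    (structurally zero when the sampling period itself carries the location).
    Returns None (NA) when neither individual was ever observed.
    """
    if a == b:
        raise ValueError("association index requires two distinct individuals")
    colocations = list(colocations)
    pa = _period_locations(colocations, a, sampling)
    pb = _period_locations(colocations, b, sampling)
    if not pa and not pb:
        return None
    x = y_ab = 0
    shared = set(pa) & set(pb)
    for key in shared:
        if pa[key] & pb[key]:
            x += 1
        else:
            y_ab += 1
    y_a = len(pa) - len(shared)
    y_b = len(pb) - len(shared)
    denom = x + y_a + y_b + y_ab
    if denom == 0:
        return None
    return x / denom


@dataclass
class AssociationNetwork:
    """Symmetric simple-ratio weights between the individuals of one year."""

    year: int
    nodes: tuple[str, ...]
    edge_weights: dict  # frozenset({a, b}) -> weight in [0, 1]

    def weight(self, a: str, b: str) -> float:
        return self.edge_weights.get(frozenset((a, b)), 0.0)


def association_network(
    colocations: Iterable[ColocationRecord],
    ids: Sequence[str],
    year: int,
    sampling: str = "day_location",
) -> AssociationNetwork:
    """All-pairs simple-ratio network over ``ids`` (zero edges omitted)."""
    colocations = list(colocations)
    ids = sorted(set(ids))
    periods = {i: _period_locations(colocations, i, sampling) for i in ids}
    weights: dict = {}
    for i, a in enumerate(ids):
        pa = periods[a]
        for b in ids[i + 1:]:
            pb = periods[b]
            if not pa and not pb:
                continue
            x = y_ab = 0
            shared = set(pa) & set(pb)
            for key in shared:
                if pa[key] & pb[key]:
                    x += 1
                else:
                    y_ab += 1
            denom = x + (len(pa) - len(shared)) + (len(pb) - len(shared)) + y_ab
            if denom and x:
                weights[frozenset((a, b))] = x / denom
    return AssociationNetwork(year=year, nodes=tuple(ids), edge_weights=weights)


# ---------------------------------------------------------------------------
# Two-level map equation
# ---------------------------------------------------------------------------

def _plogp(x: np.ndarray | float) -> np.ndarray | float:
    return np.where(x > 0, x * np.log2(np.maximum(x, 1e-300)), 0.0)


def map_equation_L(
    weights: np.ndarray, partition: Sequence[int]
) -> float:
    """Description length L(M) of a partition of an undirected weighted graph.

    ``weights`` is a symmetric non-negative matrix (zero diagonal);
    ``partition`` maps node index -> module label.  Node visit rates are the
    stationary distribution of the undirected random walk (strength /
    total strength); module exit rates are the relative weight of boundary
    edges.  L(M) = q·H(Q) + Σ_m p_m·H(P^m), computed in bits.
    """
    w = np.asarray(weights, dtype=float)
    labels = np.asarray(partition)
    total = w.sum()  # = 2 * (sum of undirected edge weights)
    if total <= 0:
        return 0.0
    p_node = w.sum(axis=1) / total
    mods, labels = np.unique(labels, return_inverse=True)
    k = len(mods)
    member = np.zeros((k, len(p_node)))
    member[labels, np.arange(len(p_node))] = 1.0
    p_mod = member @ p_node
    # within-module weight (both endpoints inside), per module
    w_in = np.einsum("mi,ij,mj->m", member, w, member)
    w_out = (member @ w.sum(axis=1)) - w_in  # boundary weight per module
    q_mod = w_out / total
    q = q_mod.sum()
    p_tot = p_mod + q_mod
    L = (
        _plogp(q)
        - 2.0 * np.sum(_plogp(q_mod))
        + np.sum(_plogp(p_tot))
        - np.sum(_plogp(p_node))
    )
    return float(L)


class _MapEqState:
    """Incremental move evaluation for greedy map-equation optimization."""

    def __init__(self, w: np.ndarray, labels: np.ndarray):
        self.w = w
        self.total = w.sum()
        self.strength = w.sum(axis=1)
        self.p_node = self.strength / self.total
        self.labels = labels.copy()
        n = len(labels)
        k = labels.max() + 1
        self.p_mod = np.zeros(k)
        self.wout_mod = np.zeros(k)
        for m in range(k):
            idx = np.flatnonzero(labels == m)
            self.p_mod[m] = self.p_node[idx].sum()
            w_in = self.w[np.ix_(idx, idx)].sum()
            self.wout_mod[m] = self.strength[idx].sum() - w_in

    def L(self) -> float:
        q_mod = self.wout_mod / self.total
        p_tot = self.p_mod + q_mod
        q = q_mod.sum()
        return float(
            _plogp(q)
            - 2.0 * np.sum(_plogp(q_mod))
            + np.sum(_plogp(p_tot))
            - np.sum(_plogp(self.p_node))
        )

    def try_moves(self, node: int) -> bool:
        """Move ``node`` to the best module among its neighbours' (or a new
        singleton) if that lowers L; returns True if moved."""
        cur = self.labels[node]
        nbr_w = self.w[node].copy()
        nbr_w[node] = 0.0  # self-loops (aggregated networks) stay internal
        k_to = np.zeros(len(self.p_mod))
        np.add.at(k_to, self.labels, nbr_w)
        candidates = set(self.labels[np.flatnonzero(nbr_w > 0)])
        candidates.discard(cur)
        # a fresh singleton module is also a candidate
        empty = np.flatnonzero(self.p_mod == 0)
        if len(empty):
            candidates.add(int(empty[0]))
        else:
            self.p_mod = np.append(self.p_mod, 0.0)
            self.wout_mod = np.append(self.wout_mod, 0.0)
            k_to = np.append(k_to, 0.0)
            candidates.add(len(self.p_mod) - 1)
        if not candidates:
            return False
        base = self.L()
        s = self.strength[node] - self.w[node, node]
        p = self.p_node[node]
        best, best_L = cur, base
        for m in candidates:
            self._apply(node, cur, m, k_to, s, p)
            trial = self.L()
            self._apply(node, m, cur, k_to, s, p)
            if trial < best_L - 1e-12:
                best, best_L = m, trial
        if best != cur:
            self._apply(node, cur, best, k_to, s, p)
            self.labels[node] = best
            return True
        return False

    def _apply(self, node, frm, to, k_to, s, p):
        self.p_mod[frm] -= p
        self.p_mod[to] += p
        self.wout_mod[frm] += 2 * k_to[frm] - s
        self.wout_mod[to] -= 2 * k_to[to] - s


def _greedy_sweep(
    w: np.ndarray, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Repeated single-node move passes until no move lowers L."""
    state = _MapEqState(w, labels)
    improved = True
    while improved:
        improved = False
        for node in rng.permutation(w.shape[0]):
            if state.try_moves(int(node)):
                improved = True
    return state.labels


def _greedy_partition(w: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One restart: node-level sweeps alternated with module aggregation.

    Single-node moves alone stall in local optima where two modules should
    merge as a unit, so converged modules are collapsed into supernodes
    (internal weight kept as a self-loop, leaving module exit/visit rates
    unchanged) and the sweep is re-run at the aggregated level, then refined
    back at node level, until the description length stops improving.
    """
    n = w.shape[0]
    labels = _greedy_sweep(w, np.arange(n), rng)
    while True:
        mods, inv = np.unique(labels, return_inverse=True)
        k = len(mods)
        if k <= 1:
            break
        member = np.zeros((k, n))
        member[inv, np.arange(n)] = 1.0
        w_agg = member @ w @ member.T
        super_labels = _greedy_sweep(w_agg, np.arange(k), rng)
        if len(np.unique(super_labels)) == k:
            break  # no merges found at the aggregated level
        labels = super_labels[inv]
        labels = _greedy_sweep(w, labels, rng)
    return labels


@dataclass
class GroupPartition:
    """Per-year assignment of individuals to social groups.

    ``groups`` lists primary member sets (disjoint); ``primary_group`` maps an
    individual to its group index; ``augmented_memberships`` lists the extra
    groups an adult male was added to (trait and fitness attribution always
    uses the primary group).  ``isolates`` are individuals with no association
    partner — they belong to no group.
    """

    year: int
    groups: list[frozenset]
    primary_group: dict
    augmented_memberships: dict = field(default_factory=dict)
    isolates: frozenset = frozenset()

    def members(self, index: int) -> frozenset:
        """Primary members plus augmented males of one group."""
        extra = {
            m for m, gs in self.augmented_memberships.items() if index in gs
        }
        return self.groups[index] | extra


def detect_groups(
    assoc: AssociationNetwork,
    seed: int = 0,
    n_trials: int = 10,
) -> GroupPartition:
    """Delineate social groups by minimizing the two-level map equation.

    Greedy node-aggregation with ``n_trials`` random-restart sweeps;
    deterministic given ``seed``.  Individuals with no positive association
    weight (network isolates) and any resulting singleton module are excluded
    from groups and reported as isolates.
    """
    ids = list(assoc.nodes)
    n = len(ids)
    if n < 2:
        raise ValueError("association network must have at least 2 nodes")
    w = np.zeros((n, n))
    index = {v: i for i, v in enumerate(ids)}
    for pair, wt in assoc.edge_weights.items():
        a, b = tuple(pair)
        w[index[a], index[b]] = wt
        w[index[b], index[a]] = wt
    strength = w.sum(axis=1)
    isolated = strength <= 0
    if isolated.all():
        warnings.warn(
            f"year {assoc.year}: all association weights zero; no groups",
            stacklevel=2,
        )
        return GroupPartition(
            year=assoc.year, groups=[], primary_group={},
            isolates=frozenset(ids),
        )
    active = np.flatnonzero(~isolated)
    sub = w[np.ix_(active, active)]
    rng = np.random.default_rng(seed)
    best_labels, best_L = None, math.inf
    for _ in range(max(1, n_trials)):
        labels = _greedy_partition(sub, rng)
        L = map_equation_L(sub, labels)
        if L < best_L - 1e-12:
            best_L, best_labels = L, labels
    groups_raw: dict = {}
    for pos, lab in enumerate(best_labels):
        groups_raw.setdefault(lab, []).append(ids[active[pos]])
    isolates = {ids[i] for i in np.flatnonzero(isolated)}
    groups: list[frozenset] = []
    for lab in sorted(groups_raw, key=lambda l: sorted(groups_raw[l])[0]):
        members = groups_raw[lab]
        if len(members) < 2:
            isolates.update(members)  # singleton module: treated as isolate
            continue
        groups.append(frozenset(members))
    primary = {m: gi for gi, grp in enumerate(groups) for m in grp}
    return GroupPartition(
        year=assoc.year,
        groups=groups,
        primary_group=primary,
        isolates=frozenset(isolates),
    )


# ---------------------------------------------------------------------------
# Adult-male multi-membership augmentation
# ---------------------------------------------------------------------------

def augment_males(
    partition: GroupPartition,
    interactions: Sequence[InteractionRecord],
    meta: Iterable[IndividualYear],
) -> GroupPartition:
    """Add adult males to every group holding ≥ 1 of their interaction partners.

    Primary assignments are untouched: a male's own network traits and fitness
    are attributed to his originally assigned group only, but his presence is
    reflected in the other groups' networks.
    """
    adult_males = {
        m.id for m in meta
        if m.year == partition.year and m.sex == "M" and m.age_class == "adult"
    }
    augmented: dict = {}
    for rec in interactions:
        for male, partner in (
            (rec.initiator, rec.recipient),
            (rec.recipient, rec.initiator),
        ):
            if male not in adult_males:
                continue
            g = partition.primary_group.get(partner)
            if g is None:
                continue
            if partition.primary_group.get(male) == g:
                continue
            augmented.setdefault(male, set()).add(g)
    return GroupPartition(
        year=partition.year,
        groups=list(partition.groups),
        primary_group=dict(partition.primary_group),
        augmented_memberships=augmented,
        isolates=partition.isolates,
    )
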