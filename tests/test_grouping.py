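"""Filtering rules, simple-ratio index, map-equation grouping, augmentation."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import exhaustive_min_L, sri_oracle
from socsel.grouping import (
    AssociationNetwork,
    association_network,
    augment_males,
    detect_groups,
    filter_interactions,
    map_equation_L,
    simple_ratio_index,
)
from socsel.records import (
    UNKNOWN,
    ColocationRecord,
    IndividualYear,
    InteractionRecord,
)

YEAR = 2010


def day(month, d):
    return dt.date(YEAR, month, d).toordinal()


def meta(id, sex="F", age="adult", n_obs=10):
    return IndividualYear(id, YEAR, sex, age, "colA", "higher", None, None, n_obs)


def inter(a, b, month=5, d=10, behaviour="affiliative"):
    return InteractionRecord(a, b, day(month, d), "siteX", behaviour)


# ---------------------------------------------------------------------------
# filter_interactions
# ---------------------------------------------------------------------------

class TestFiltering:
    META = [meta("a"), meta("b"), meta("c", n_obs=4), meta("d", n_obs=5)]

    def test_season_rule_removes_july(self):
        kept, rep = filter_interactions(
            [inter("a", "b", month=7, d=15), inter("a", "b", month=6)],
            self.META, YEAR,
        )
        assert len(kept) == 1 and rep.removed_by("season") == 1

    def test_unknown_participant_removed(self):
        kept, rep = filter_interactions(
            [inter("a", UNKNOWN), inter(UNKNOWN, "b")], self.META, YEAR
        )
        assert kept == [] and rep.removed_by("identity") == 2

    def test_observation_threshold_boundary_keeps_five(self):
        kept, rep = filter_interactions(
            [inter("a", "c"), inter("a", "d")], self.META, YEAR
        )
        # c has 4 observations (removed); d has exactly 5 (kept)
        assert [r.recipient for r in kept] == ["d"]
        assert rep.removed_by("min_observations") == 1

    def test_non_affiliative_removed(self):
        kept, rep = filter_interactions(
            [inter("a", "b", behaviour="agonistic"), inter("a", "b")],
            self.META, YEAR,
        )
        assert len(kept) == 1 and rep.removed_by("behaviour") == 1

    def test_report_reconciles_counts(self):
        records = [
            inter("a", "b"), inter("a", UNKNOWN), inter("a", "c"),
            inter("b", "a", month=8), inter("a", "b", behaviour="other"),
        ]
        kept, rep = filter_interactions(records, self.META, YEAR)
        assert rep.total_in == len(records)
        assert rep.retained == len(kept)
        assert rep.total_removed + rep.retained == rep.total_in

    def test_idempotent(self):
        records = [
            inter("a", "b"), inter("a", UNKNOWN), inter("a", "c"),
            inter("b", "a", month=7), inter("a", "b", behaviour="agonistic"),
        ]
        once, _ = filter_interactions(records, self.META, YEAR)
        twice, rep2 = filter_interactions(once, self.META, YEAR)
        assert twice == once and rep2.total_removed == 0


# ---------------------------------------------------------------------------
# simple_ratio_index
# ---------------------------------------------------------------------------

def coloc(ind, d, loc="siteX"):
    return ColocationRecord(ind, day(4, 1) + d, loc)


class TestSimpleRatio:
    def test_formula_value(self):
        # x=3 joint periods, y_a=1, y_b=2 -> 3/6 = 0.5
        records = (
            [coloc("a", d) for d in (0, 1, 2)]
            + [coloc("b", d) for d in (0, 1, 2)]
            + [coloc("a", 3)]
            + [coloc("b", d, "siteY") for d in (4, 5)]
        )
        assert simple_ratio_index(records, "a", "b") == pytest.approx(0.5)

    def test_always_together_is_one(self):
        records = [coloc(i, d) for i in "ab" for d in range(5)]
        assert simple_ratio_index(records, "a", "b") == 1.0

    def test_never_together_is_zero(self):
        records = [coloc("a", d) for d in range(3)] + [
            coloc("b", d + 10) for d in range(3)
        ]
        assert simple_ratio_index(records, "a", "b") == 0.0

    def test_never_observed_is_na(self):
        assert simple_ratio_index([coloc("c", 0)], "a", "b") is None

    def test_same_individual_rejected(self):
        with pytest.raises(ValueError):
            simple_ratio_index([], "a", "a")

    @given(st.data())
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_symmetry_and_duplicate_invariance(self, data):
        obs = data.draw(
            st.lists(
                st.tuples(
                    st.sampled_from(["a", "b", "c"]),
                    st.integers(0, 5),
                    st.sampled_from(["x", "y"]),
                ),
                min_size=1,
                max_size=20,
            )
        )
        records = [coloc(i, d, l) for i, d, l in obs]
        sri_ab = simple_ratio_index(records, "a", "b")
        sri_ba = simple_ratio_index(records, "b", "a")
        assert sri_ab == sri_ba
        # duplicated rows within a sampling period change nothing
        doubled = records + records
        assert simple_ratio_index(doubled, "a", "b") == sri_ab
        # agreement with the independent period-counting oracle
        expected = sri_oracle(obs, "a", "b")
        if expected is None:
            assert sri_ab is None
        else:
            assert sri_ab == pytest.approx(expected)


def test_association_network_matches_pairwise_index():
    records = (
        [coloc(i, d) for i in "ab" for d in range(4)]
        + [coloc("c", d, "siteY") for d in range(4)]
        + [coloc("a", 9, "siteY")]
    )
    net = association_network(records, ["a", "b", "c"], YEAR)
    for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
        expected = simple_ratio_index(records, x, y) or 0.0
        assert net.weight(x, y) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# detect_groups / map equation
# ---------------------------------------------------------------------------

def assoc_from_matrix(w, ids=None):
    n = len(w)
    ids = ids or [f"n{i}" for i in range(n)]
    ew = {
        frozenset((ids[i], ids[j])): w[i][j]
        for i in range(n)
        for j in range(i + 1, n)
        if w[i][j] > 0
    }
    return AssociationNetwork(YEAR, tuple(ids), ew)


def two_cliques(weight_bridge=0.05):
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i < j:
                    w[i, j] = w[j, i] = 1.0
    w[3, 4] = w[4, 3] = weight_bridge
    return w


class TestDetectGroups:
    def test_disconnected_triangles_are_two_groups(self):
        w = np.zeros((6, 6))
        for block in (range(3), range(3, 6)):
            for i in block:
                for j in block:
                    if i < j:
                        w[i, j] = w[j, i] = 0.5
        part = detect_groups(assoc_from_matrix(w), seed=0)
        assert sorted(sorted(g) for g in part.groups) == [
            ["n0", "n1", "n2"], ["n3", "n4", "n5"],
        ]

    def test_weakly_bridged_cliques_split(self):
        part = detect_groups(assoc_from_matrix(two_cliques()), seed=0)
        assert sorted(sorted(g) for g in part.groups) == [
            ["n0", "n1", "n2", "n3"], ["n4", "n5", "n6", "n7"],
        ]

    def test_single_clique_is_one_group(self):
        w = np.ones((5, 5)) - np.eye(5)
        part = detect_groups(assoc_from_matrix(w), seed=0)
        assert len(part.groups) == 1
        # exhaustive search agrees that one module is optimal
        _, best_L = exhaustive_min_L(w, map_equation_L)
        assert map_equation_L(w, np.zeros(5, int)) == pytest.approx(best_L)

    def test_matches_exhaustive_minimum(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 8))
            w = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.6:
                        w[i, j] = w[j, i] = rng.random()
            if w.sum() == 0:
                continue
            part = detect_groups(assoc_from_matrix(w), seed=trial)
            active = np.flatnonzero(w.sum(1) > 0)
            _, best_L = exhaustive_min_L(
                w[np.ix_(active, active)], map_equation_L
            )
            labels = np.empty(len(active), dtype=int)
            nxt = len(part.groups)
            for pos, i in enumerate(active):
                g = part.primary_group.get(f"n{i}")
                if g is None:
                    g, nxt = nxt, nxt + 1
                labels[pos] = g
            mine = map_equation_L(w[np.ix_(active, active)], labels)
            assert mine == pytest.approx(best_L, abs=1e-9)

    def test_weight_scaling_invariance(self, rng):
        w = two_cliques(0.2)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        assert map_equation_L(w, labels) == pytest.approx(
            map_equation_L(10.0 * w, labels)
        )
        p1 = detect_groups(assoc_from_matrix(w), seed=3)
        # scale weights into (0, 1] to stay a valid association network
        p2 = detect_groups(assoc_from_matrix(0.37 * w), seed=3)
        assert sorted(map(sorted, p1.groups)) == sorted(map(sorted, p2.groups))

    def test_all_zero_weights_yield_isolates_with_warning(self):
        assoc = AssociationNetwork(YEAR, ("a", "b", "c"), {})
        with pytest.warns(UserWarning, match="zero"):
            part = detect_groups(assoc, seed=0)
        assert part.groups == [] and part.isolates == {"a", "b", "c"}

    def test_deterministic_given_seed(self, rng):
        w = np.abs(rng.normal(size=(10, 10)))
        w = np.triu(w, 1)
        w = w + w.T
        a = detect_groups(assoc_from_matrix(w), seed=7)
        b = detect_groups(assoc_from_matrix(w), seed=7)
        assert a.groups == b.groups


# ---------------------------------------------------------------------------
# augment_males
# ---------------------------------------------------------------------------

class TestAugmentation:
    META = [
        meta("m1", sex="M"), meta("m2", sex="M", age="yearling"),
        meta("f1"), meta("f2"), meta("f3"), meta("f4"),
    ]

    def partition(self):
        from socsel.grouping import GroupPartition

        groups = [frozenset({"m1", "f1", "f2"}), frozenset({"f3", "f4", "m2"})]
        return GroupPartition(
            YEAR, groups,
            {m: gi for gi, g in enumerate(groups) for m in g},
        )

    def test_adult_male_gains_secondary_membership(self):
        part = augment_males(self.partition(), [inter("m1", "f3")], self.META)
        assert part.augmented_memberships == {"m1": {1}}
        assert part.primary_group["m1"] == 0
        assert part.members(1) == {"f3", "f4", "m2", "m1"}

    def test_female_cross_group_interaction_ignored(self):
        part = augment_males(self.partition(), [inter("f1", "f3")], self.META)
        assert part.augmented_memberships == {}

    def test_yearling_male_not_augmented(self):
        part = augment_males(self.partition(), [inter("m2", "f1")], self.META)
        assert part.augmented_memberships == {}

    def test_male_without_cross_interactions_unchanged(self):
        part = augment_males(self.partition(), [inter("m1", "f2")], self.META)
        assert part.augmented_memberships == {}
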