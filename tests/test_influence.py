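"""Influence analytics checked against brute-force path enumeration.

The oracle enumerates directed length-1 and length-2 paths explicitly
with Python loops, independently of the vectorized implementation.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossimpact import (
    CrossImpactMatrix,
    GoalSet,
    ValidationError,
    competition_ranks,
    focal_goal_report,
    in_degree,
    out_degree,
    perturbation_analysis,
    second_order_influence,
    summarize,
    total_influence,
)
from crossimpact.errors import LookupError_

from .conftest import random_matrix


def brute_second_order(m, a, d):
    """Sum of w[a,i]*w[i,d] over every explicit length-2 path a -> i -> d."""
    total = 0
    for i in m.goal_set.goals:
        if i in (a, d):
            continue
        total += m[a, i] * m[i, d]
    return total


def brute_total(m, g):
    """Out-degree plus weight-propagated neighbour out-degrees, by loops."""
    d_out = {
        x: sum(m[x, j] for j in m.goal_set.goals if j != x)
        for x in m.goal_set.goals
    }
    return d_out[g] + sum(
        m[g, j] * d_out[j] for j in m.goal_set.goals if j != g
    )


class TestDegrees:
    def test_hand_worked_row_and_column_sums(self, abc_matrix):
        assert out_degree(abc_matrix, "A") == 3   # 1 + 2
        assert in_degree(abc_matrix, "C") == 5    # 2 + 3

    def test_uniform_plus3(self, plus3_16):
        for g in plus3_16.goal_set:
            assert out_degree(plus3_16, g) == 45
            assert in_degree(plus3_16, g) == 45

    def test_zero_matrix(self, zero16):
        assert out_degree(zero16, "SDG5") == 0
        assert in_degree(zero16, "SDG5") == 0

    def test_unknown_goal(self, abc_matrix):
        with pytest.raises(LookupError_):
            out_degree(abc_matrix, "Z")

    def test_grand_sum_identity(self):
        rng = np.random.default_rng(11)
        m = random_matrix(7, rng)
        assert sum(out_degree(m, g) for g in m.goal_set) == sum(
            in_degree(m, g) for g in m.goal_set
        )


class TestSecondOrder:
    def test_single_path_by_hand(self, abc_matrix):
        # only path A -> B -> C contributes: 1 * 3
        assert second_order_influence(abc_matrix, "A", "C") == 3

    def test_same_goal_rejected(self, abc_matrix):
        with pytest.raises(ValidationError):
            second_order_influence(abc_matrix, "A", "A")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = random_matrix(n, rng)
        goals = m.goal_set.goals
        a, d = goals[0], goals[-1]
        assert second_order_influence(m, a, d) == brute_second_order(m, a, d)


class TestTotalInfluence:
    def test_two_goal_by_hand(self):
        m = CrossImpactMatrix(GoalSet(["A", "B"]), [[0, 2], [3, 0]])
        assert total_influence(m, "A") == 8  # 2 + 2*3

    def test_three_goal_by_hand(self, abc_matrix):
        # 3 + 1*3 + 2*(-1)
        assert total_influence(abc_matrix, "A") == 4

    def test_uniform_plus3_closed_form(self, plus3_16):
        # c(G-1) + c^2 (G-1)^2 with c=3, G=16
        for g in plus3_16.goal_set:
            assert total_influence(plus3_16, g) == 2070

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_matches_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        m = random_matrix(n, rng)
        for g in m.goal_set.goals:
            assert total_influence(m, g) == brute_total(m, g)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_negation_identity(self, seed):
        # I^Total(-w) = -D^Out + sum w * D^Out: the second-order term is
        # invariant under negation while the first-order term flips sign.
        rng = np.random.default_rng(seed)
        m = random_matrix(5, rng)
        neg = CrossImpactMatrix(m.goal_set, -m.weights)
        for g in m.goal_set.goals:
            d_out = out_degree(m, g)
            second = total_influence(m, g) - d_out
            assert total_influence(neg, g) == -d_out + second
            assert out_degree(neg, g) == -d_out
            assert in_degree(neg, g) == -in_degree(m, g)


class TestRanking:
    def test_competition_style_shared_ranks(self):
        assert competition_ranks([10, 8, 8, 5]) == [1, 2, 2, 4]
        assert competition_ranks([5, 5, 5]) == [1, 1, 1]

    def test_all_zero_matrix_everything_tied(self, zero16):
        s = summarize(zero16)
        assert all(r == 1 for r in s.rank_first_order.values())
        assert all(r == 1 for r in s.rank_total.values())

    def test_distinct_row_sums_rank_equals_sort_order(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_matrix(6, rng)
            s = summarize(m)
            d = s.out_degrees
            if len(set(d.values())) < len(d):
                continue
            expected = {
                g: 1 + sorted(d.values(), reverse=True).index(d[g])
                for g in d
            }
            assert s.rank_first_order == expected

    def test_bounds_from_scale(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(2, 8))
            m = random_matrix(n, rng)
            s = summarize(m)
            for g in m.goal_set.goals:
                assert abs(s.out_degrees[g]) <= 3 * (n - 1)
                assert abs(s.in_degrees[g]) <= 3 * (n - 1)
                assert abs(s.total_influences[g]) <= 3 * (n - 1) + 9 * (n - 1) ** 2

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(6, rng)
        order = list(m.goal_set.goals)
        rng.shuffle(order)
        s, sp = summarize(m), summarize(m.permuted(order))
        assert s.out_degrees == sp.out_degrees
        assert s.in_degrees == sp.in_degrees
        assert s.total_influences == sp.total_influences
        assert s.rank_total == sp.rank_total
        assert s.rank_first_order == sp.rank_first_order

    def test_table_sorted_by_total_rank(self, abc_matrix):
        df = summarize(abc_matrix).table()
        assert list(df["rank_total"]) == sorted(df["rank_total"])


class TestFocalGoalReport:
    def test_zero_matrix_all_empty(self, zero16):
        r = focal_goal_report(zero16, "SDG3")
        assert all(v == 0 for v in r.net_on.values())
        assert all(v == 0 for v in r.net_from.values())
        assert r.feedback_pairs == ()

    def test_mutual_direct_positive_is_feedback(self):
        m = CrossImpactMatrix(
            GoalSet(["A", "B", "C"]), [[0, 2, 0], [1, 0, 0], [0, 0, 0]]
        )
        r = focal_goal_report(m, "A")
        assert r.net_on["B"] == 2
        assert r.net_from["B"] == 1
        assert r.feedback_pairs == ("B",)
        assert "A" not in r.net_on

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_net_values_match_direct_plus_path_sums(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(6, rng)
        focal = m.goal_set.goals[int(rng.integers(6))]
        r = focal_goal_report(m, focal)
        for j in r.net_on:
            assert r.net_on[j] == m[focal, j] + brute_second_order(m, focal, j)
            assert r.net_from[j] == m[j, focal] + brute_second_order(m, j, focal)

    def test_feedback_threshold_configurable(self):
        m = CrossImpactMatrix(
            GoalSet(["A", "B", "C"]), [[0, 1, 0], [1, 0, 0], [0, 0, 0]]
        )
        assert focal_goal_report(m, "A", feedback_threshold=0).feedback_pairs == ("B",)
        assert focal_goal_report(m, "A", feedback_threshold=1).feedback_pairs == ()


class TestPerturbation:
    def test_zero_probability_retains_all_ranks(self):
        rng = np.random.default_rng(2)
        m = random_matrix(6, rng)
        res = perturbation_analysis(m, p=0.0, n_replicates=10, seed=0)
        assert all(f == 1.0 for f in res.retention_frequency.values())

    def test_frequencies_bounded_and_deterministic(self):
        rng = np.random.default_rng(4)
        m = random_matrix(8, rng)
        r1 = perturbation_analysis(m, p=0.2, n_replicates=30, seed=17)
        r2 = perturbation_analysis(m, p=0.2, n_replicates=30, seed=17)
        assert r1 == r2
        assert all(0.0 <= f <= 1.0 for f in r1.retention_frequency.values())
        assert r1.n_replicates == 30

    @pytest.mark.parametrize("bad", [{"p": -0.1}, {"p": 1.5}, {"n_replicates": 0}])
    def test_invalid_settings_rejected(self, abc_matrix, bad):
        with pytest.raises(ValidationError):
            perturbation_analysis(abc_matrix, **bad)
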