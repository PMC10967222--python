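"""Network influence analytics on the cross-impact matrix.

First-order influence of a goal is its out-degree, the row sum of the
signed weight matrix:

    D_g^Out = sum_j w[g, j]

Second-order influence of goal A on goal D propagates through one
intermediate goal, summing over all directed length-2 paths:

    I2(A -> D) = sum_i w[A, i] * w[i, D]

and a goal's total (first- plus second-order) influence on the network is

    I_g^Total = D_g^Out + sum_{j != g} w[g, j] * D_j^Out.

The zero diagonal makes the i = A and i = D terms vanish, so no
self-loops ever contribute.  Truncation at second order is deliberate:
the method ranks goals by direct plus once-mediated influence, not by an
infinite-order centrality.  All quantities are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .model import SCORE_MAX, SCORE_MIN, CrossImpactMatrix


def out_degree(matrix: CrossImpactMatrix, goal: str) -> int:
    """Row sum of ``goal``: its aggregate direct influence on the network."""
    i = matrix.goal_set.index(goal)
    return int(matrix.weights[i, :].sum())


def in_degree(matrix: CrossImpactMatrix, goal: str) -> int:
    """Column sum of ``goal``: aggregate direct influence it receives."""
    i = matrix.goal_set.index(goal)
    return int(matrix.weights[:, i].sum())


def second_order_influence(matrix: CrossImpactMatrix, a: str, d: str) -> int:
    """Influence of ``a`` on ``d`` through one intermediate goal.

    Equals ``sum_i w[a, i] * w[i, d]``, i.e. the (a, d) entry of the
    squared weight matrix.  ``a`` and ``d`` must differ.
    """
    ia = matrix.goal_set.index(a)
    id_ = matrix.goal_set.index(d)
    if ia == id_:
        raise ValidationError(f"second-order influence of {a} on itself is undefined")
    w = matrix.weights
    return int(w[ia, :] @ w[:, id_])


def total_influence(matrix: CrossImpactMatrix, goal: str) -> int:
    """First- plus second-order influence of ``goal`` on the whole network."""
    i = matrix.goal_set.index(goal)
    w = matrix.weights
    d_out = w.sum(axis=1)
    return int(d_out[i] + w[i, :] @ d_out)


def competition_ranks(values: Sequence[int]) -> list[int]:
    """Descending competition ranking ("1224"): ties share a rank.

    A value's rank is one plus the number of strictly larger values.
    """
    arr = np.asarray(values)
    return [int(1 + np.sum(arr > v)) for v in arr]


@dataclass(frozen=True)
class InfluenceSummary:
    """Per-goal degrees, total influence and rankings for one matrix."""

    goals: tuple[str, ...]
    out_degrees: Mapping[str, int]
    in_degrees: Mapping[str, int]
    total_influences: Mapping[str, int]
    rank_first_order: Mapping[str, int]
    rank_total: Mapping[str, int]

    def table(self):
        """Ranking table as a DataFrame, ordered by total-influence rank.

        Ties are displayed in goal-set order; tied goals share a rank.
        """
        import pandas as pd

        rows = sorted(
            self.goals,
            key=lambda g: (self.rank_total[g], self.goals.index(g)),
        )
        return pd.DataFrame(
            {
                "goal": rows,
                "out_degree": [self.out_degrees[g] for g in rows],
                "in_degree": [self.in_degrees[g] for g in rows],
                "total_influence": [self.total_influences[g] for g in rows],
                "rank_first_order": [self.rank_first_order[g] for g in rows],
                "rank_total": [self.rank_total[g] for g in rows],
            }
        )


def summarize(matrix: CrossImpactMatrix) -> InfluenceSummary:
    """Compute all per-goal influence metrics and both rankings."""
    goals = matrix.goal_set.goals
    w = matrix.weights
    d_out = w.sum(axis=1)
    d_in = w.sum(axis=0)
    total = d_out + w @ d_out
    return InfluenceSummary(
        goals=goals,
        out_degrees={g: int(d_out[i]) for i, g in enumerate(goals)},
        in_degrees={g: int(d_in[i]) for i, g in enumerate(goals)},
        total_influences={g: int(total[i]) for i, g in enumerate(goals)},
        rank_first_order=dict(zip(goals, competition_ranks(d_out))),
        rank_total=dict(zip(goals, competition_ranks(total))),
    )


@dataclass(frozen=True)
class FocalGoalReport:
    """Direct and net (direct + second-order) influence of/on one goal.

    ``feedback_pairs`` lists partner goals locked in a positive feedback
    loop with the focal goal: net influence positive in both directions.
    """

    focal: str
    direct_on: Mapping[str, int]
    direct_from: Mapping[str, int]
    net_on: Mapping[str, int]
    net_from: Mapping[str, int]
    feedback_pairs: tuple[str, ...]


def focal_goal_report(
    matrix: CrossImpactMatrix, focal: str, feedback_threshold: int = 0
) -> FocalGoalReport:
    """Report how ``focal`` influences, and is influenced by, every other goal.

    Net influence combines the direct score with the second-order term:
    ``net_on[j] = w[F, j] + I2(F -> j)`` and symmetrically for
    ``net_from``.  A partner enters ``feedback_pairs`` when both net
    values exceed ``feedback_threshold`` (strict inequality; default 0,
    i.e. strictly positive both ways).
    """
    f = matrix.goal_set.index(focal)
    focal_code = matrix.goal_set.goals[f]
    others = [g for g in matrix.goal_set.goals if g != focal_code]
    direct_on = {j: matrix[focal_code, j] for j in others}
    direct_from = {j: matrix[j, focal_code] for j in others}
    net_on = {
        j: direct_on[j] + second_order_influence(matrix, focal_code, j)
        for j in others
    }
    net_from = {
        j: direct_from[j] + second_order_influence(matrix, j, focal_code)
        for j in others
    }
    feedback = tuple(
        j for j in others
        if net_on[j] > feedback_threshold and net_from[j] > feedback_threshold
    )
    return FocalGoalReport(
        focal=focal_code,
        direct_on=direct_on,
        direct_from=direct_from,
        net_on=net_on,
        net_from=net_from,
        feedback_pairs=feedback,
    )


@dataclass(frozen=True)
class PerturbationResult:
    """Rank-stability summary from Monte Carlo perturbation of the matrix."""

    n_replicates: int
    noise_spec: str
    metric: str
    retention_frequency: Mapping[str, float]
    rank_distribution: Mapping[str, Mapping[int, int]] = field(default_factory=dict)


def perturbation_analysis(
    matrix: CrossImpactMatrix,
    p: float = 0.1,
    n_replicates: int = 100,
    seed: int = 0,
    metric: str = "total",
) -> PerturbationResult:
    """Estimate how stable the influence ranking is to small score changes.

    Each off-diagonal cell is independently shifted by ±1 with
    probability ``p`` (direction equiprobable), clipped to the
    seven-point scale; the chosen ranking metric (``"total"`` or
    ``"first_order"``) is recomputed on each perturbed matrix and, per
    goal, the frequency of retaining its unperturbed rank is reported.
    Deterministic for a fixed seed.
    """
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"perturbation probability must be in [0, 1], got {p}")
    if not isinstance(n_replicates, int) or n_replicates < 1:
        raise ValidationError(f"n_replicates must be a positive integer, got {n_replicates}")
    if metric not in ("total", "first_order"):
        raise ValidationError(f"metric must be 'total' or 'first_order', got {metric!r}")

    rng = np.random.default_rng(seed)
    goals = matrix.goal_set.goals
    base = summarize(matrix)
    base_rank = base.rank_total if metric == "total" else base.rank_first_order

    G = len(goals)
    off = ~np.eye(G, dtype=bool)
    retained = {g: 0 for g in goals}
    dist: dict[str, dict[int, int]] = {g: {} for g in goals}
    for _ in range(n_replicates):
        w = matrix.weights.copy()
        hit = off & (rng.random((G, G)) < p)
        shift = rng.choice([-1, 1], size=(G, G))
        w[hit] = np.clip(w[hit] + shift[hit], SCORE_MIN, SCORE_MAX)
        s = summarize(CrossImpactMatrix(matrix.goal_set, w))
        ranks = s.rank_total if metric == "total" else s.rank_first_order
        for g in goals:
            r = ranks[g]
            dist[g][r] = dist[g].get(r, 0) + 1
            if r == base_rank[g]:
                retained[g] += 1
    freq = {g: retained[g] / n_replicates for g in goals}
    return PerturbationResult(
        n_replicates=n_replicates,
        noise_spec=f"per-cell +-1 shift with p={p}, clipped to [{SCORE_MIN},{SCORE_MAX}]",
        metric=metric,
        retention_frequency=freq,
        rank_distribution={g: dict(sorted(d.items())) for g, d in dist.items()},
    )
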