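"""Synthetic workshops and matrices for testing the full pipeline.

The real input to this analysis is a scored cross-impact matrix produced
in a participatory workshop; such matrices are rarely deposited as data.
This module generates matrices and whole mock workshops with the same
statistical structure — a configurable mixture of promoting, neutral and
restricting interactions; integer magnitudes 1–3; several scoring groups
with cross-review and a controllable disagreement rate — so that every
stage of the pipeline is testable end to end.

Defaults mirror the study configuration this package was built around:
16 goals (240 ordered pairs) with 213 promoting, 20 neutral and 7
restricting interactions, scored by five groups.  Score magnitudes are
drawn uniformly from {1, 2, 3} because the sign mixture constrains only
the signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, ValidationError
from .model import (
    SCORE_MAX,
    SCORE_MIN,
    CrossImpactMatrix,
    GoalSet,
    ScoreRecord,
    count_pairs,
)

#: Sign mixture observed in the study: (restricting, none, promoting).
DEFAULT_SIGN_COUNTS = (7, 20, 213)


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a synthetic workshop.

    Exactly one of ``sign_counts`` (exact class sizes, deterministic) or
    ``sign_probs`` (per-cell class probabilities) governs the sign
    mixture.  ``magnitude_dist`` gives the probabilities of magnitudes
    1, 2, 3 for nonzero scores.
    """

    n_goals: int = 16
    sign_counts: tuple[int, int, int] | None = DEFAULT_SIGN_COUNTS
    sign_probs: tuple[float, float, float] | None = None
    magnitude_dist: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_groups: int = 5
    discrepancy_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_goals < 2:
            raise ConfigurationError("n_goals must be >= 2")
        n_pairs = self.n_goals * (self.n_goals - 1)
        if (self.sign_counts is None) == (self.sign_probs is None):
            raise ConfigurationError(
                "exactly one of sign_counts or sign_probs must be given"
            )
        if self.sign_counts is not None:
            counts = tuple(int(c) for c in self.sign_counts)
            if len(counts) != 3 or any(c < 0 for c in counts):
                raise ConfigurationError("sign_counts must be 3 non-negative integers")
            if sum(counts) != n_pairs:
                raise ValidationError(
                    f"sign_counts {counts} must sum to G*(G-1) = {n_pairs}"
                )
            object.__setattr__(self, "sign_counts", counts)
        if self.sign_probs is not None:
            probs = tuple(float(p) for p in self.sign_probs)
            if len(probs) != 3 or any(p < 0 for p in probs):
                raise ConfigurationError("sign_probs must be 3 non-negative numbers")
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValidationError(f"sign_probs must sum to 1, got {sum(probs)}")
            object.__setattr__(self, "sign_probs", probs)
        mag = tuple(float(p) for p in self.magnitude_dist)
        if len(mag) != 3 or any(p < 0 for p in mag) or abs(sum(mag) - 1.0) > 1e-9:
            raise ConfigurationError(
                "magnitude_dist must be 3 probabilities over magnitudes {1,2,3}"
            )
        object.__setattr__(self, "magnitude_dist", mag)
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if not 0.0 <= self.discrepancy_rate <= 1.0:
            raise ValidationError("discrepancy_rate must be in [0, 1]")

    def goal_set(self) -> GoalSet:
        return GoalSet.sdg_default(self.n_goals)


@dataclass(frozen=True)
class SyntheticWorkshop:
    """A generated workshop: ground truth plus the two scoring stages.

    ``injected_discrepancies`` maps exactly the pairs where the review
    copy was perturbed to the perturbed (review) value, so tests can
    verify discrepancy detection against construction.
    """

    truth: CrossImpactMatrix
    initial: tuple[ScoreRecord, ...]
    review: tuple[ScoreRecord, ...]
    injected_discrepancies: Mapping[tuple[str, str], int]
    pair_assignment: Mapping[tuple[str, str], tuple[str, str]]


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    # Independent sub-streams so e.g. changing the group count cannot
    # reshuffle the matrix cells.
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_matrix(config: SyntheticConfig) -> CrossImpactMatrix:
    """Generate a cross-impact matrix with the configured sign mixture.

    In counts mode the requested class sizes are met exactly: the signs
    are assigned by a uniform random placement over the off-diagonal
    cells.  In probability mode each cell draws its class independently.
    Deterministic under a fixed seed.
    """
    rng = _rng_streams(config.seed, 3)[0]
    goal_set = config.goal_set()
    G = config.n_goals
    n_pairs = count_pairs(goal_set)

    if config.sign_counts is not None:
        n_neg, n_zero, n_pos = config.sign_counts
        signs = np.concatenate(
            [np.full(n_neg, -1), np.zeros(n_zero, dtype=int), np.full(n_pos, 1)]
        )
        rng.shuffle(signs)
    else:
        signs = rng.choice([-1, 0, 1], size=n_pairs, p=config.sign_probs)

    magnitudes = rng.choice([1, 2, 3], size=n_pairs, p=config.magnitude_dist)
    w = np.zeros((G, G), dtype=np.int64)
    k = 0
    for i in range(G):
        for j in range(G):
            if i == j:
                continue
            w[i, j] = signs[k] * magnitudes[k]
            k += 1
    return CrossImpactMatrix(goal_set, w)


def _perturb_score(score: int, rng: np.random.Generator) -> int:
    # +-1 shift, clipped to scale, guaranteed to differ from the input.
    candidates = [
        c for c in (score - 1, score + 1) if SCORE_MIN <= c <= SCORE_MAX
    ]
    return int(rng.choice(candidates))


def generate_workshop(config: SyntheticConfig) -> SyntheticWorkshop:
    """Generate a full mock workshop around a ground-truth matrix.

    Ordered pairs are dealt round-robin to the scoring groups; the
    reviewing group for each pair is the next group in cyclic order, so
    scorer and reviewer always differ when there are at least two
    groups.  Each pair's review score is independently perturbed with
    probability ``discrepancy_rate`` (±1, clipped, never equal to the
    initial score).
    """
    if config.discrepancy_rate > 0 and config.n_groups < 2:
        raise ConfigurationError(
            "cross-review needs at least 2 groups; got n_groups=1 with a "
            "nonzero discrepancy rate"
        )
    _, rng_perturb, _ = _rng_streams(config.seed, 3)
    truth = generate_matrix(config)
    goal_set = truth.goal_set
    pairs = goal_set.ordered_pairs()

    assignment: dict[tuple[str, str], tuple[str, str]] = {}
    for k, pair in enumerate(pairs):
        scorer = k % config.n_groups
        reviewer = (scorer + 1) % config.n_groups if config.n_groups >= 2 else scorer
        assignment[pair] = (f"group{scorer + 1}", f"group{reviewer + 1}")

    initial = []
    review = []
    injected: dict[tuple[str, str], int] = {}
    for pair in pairs:
        s, t = pair
        true_score = truth[s, t]
        scorer, reviewer = assignment[pair]
        initial.append(
            ScoreRecord(
                s, t, true_score,
                motivation=f"synthetic rationale for {s}->{t}",
                group=scorer, stage="initial",
            )
        )
        review_score = true_score
        if rng_perturb.random() < config.discrepancy_rate:
            review_score = _perturb_score(true_score, rng_perturb)
            injected[pair] = review_score
        review.append(
            ScoreRecord(
                s, t, review_score,
                motivation=f"synthetic review of {s}->{t}",
                group=reviewer, stage="review",
            )
        )
    return SyntheticWorkshop(
        truth=truth,
        initial=tuple(initial),
        review=tuple(review),
        injected_discrepancies=injected,
        pair_assignment=assignment,
    )
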