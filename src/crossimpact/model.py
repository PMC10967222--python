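"""Domain model: goal sets, score records and the signed cross-impact matrix.

The central object is :class:`CrossImpactMatrix`, a G×G integer matrix
``w`` in which entry ``w[g, j]`` scores how progress on goal *g* influences
progress on goal *j* on a seven-point scale from −3 (strongly restricting)
to +3 (strongly promoting).  Rows are the influencing goals, columns the
influenced goals.  The diagonal is structurally zero: self-interactions
are never scored, so a complete study of G goals scores exactly
``G·(G−1)`` ordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    ConflictError,
    IncompleteMatrixError,
    LookupError_,
    ValidationError,
)

SCORE_MIN = -3
SCORE_MAX = 3

STAGES = ("initial", "review", "final")


def normalize_goal_id(raw: str) -> str:
    """Normalize a goal identifier to the canonical upper-case form.

    ``"sdg3"``, ``" SDG 3 "`` and ``"SDG3"`` all map to ``"SDG3"``; other
    strings are upper-cased and stripped, so the model is usable with
    arbitrary goal codes, not just SDGs.
    """
    code = str(raw).strip().upper().replace(" ", "")
    return code


def _validate_score(score) -> int:
    if isinstance(score, bool):
        raise ValidationError(f"score must be an integer, got {score!r}")
    if isinstance(score, float):
        if not score.is_integer():
            raise ValidationError(
                f"score must be an integer on the seven-point scale, got {score!r}"
            )
        score = int(score)
    if not isinstance(score, (int, np.integer)):
        raise ValidationError(f"score must be an integer, got {score!r}")
    score = int(score)
    if not SCORE_MIN <= score <= SCORE_MAX:
        raise ValidationError(
            f"score {score} outside the seven-point scale [{SCORE_MIN}, {SCORE_MAX}]"
        )
    return score


@dataclass(frozen=True)
class GoalSet:
    """Ordered collection of goal identifiers defining the matrix axes.

    Parameters
    ----------
    goals:
        Goal codes in a fixed, significant order (row/column order of the
        matrix).  Codes are normalized via :func:`normalize_goal_id`.
    labels:
        Optional mapping from goal code to a display label.
    """

    goals: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __init__(self, goals: Sequence[str], labels: Mapping[str, str] | None = None):
        norm = tuple(normalize_goal_id(g) for g in goals)
        if len(norm) < 2:
            raise ValidationError("a goal set needs at least 2 goals")
        if len(set(norm)) != len(norm):
            dupes = sorted({g for g in norm if norm.count(g) > 1})
            raise ValidationError(f"duplicate goal identifiers: {dupes}")
        object.__setattr__(self, "goals", norm)
        norm_labels = {
            normalize_goal_id(k): str(v) for k, v in (labels or {}).items()
        }
        object.__setattr__(self, "labels", norm_labels)

    @classmethod
    def sdg_default(cls, n: int = 16) -> "GoalSet":
        """The 2030-Agenda goal set used by default: SDG 1–16.

        SDG 17 (partnerships for the goals) is omitted from the default
        because it is too broad to score pairwise in a meaningful way;
        pass ``n=17`` to include it anyway.
        """
        labels = {f"SDG{i}": _SDG_LABELS.get(i, f"Goal {i}") for i in range(1, n + 1)}
        return cls([f"SDG{i}" for i in range(1, n + 1)], labels)

    def __len__(self) -> int:
        return len(self.goals)

    def __iter__(self):
        return iter(self.goals)

    def __contains__(self, goal) -> bool:
        return normalize_goal_id(goal) in self.goals

    def index(self, goal: str) -> int:
        code = normalize_goal_id(goal)
        try:
            return self.goals.index(code)
        except ValueError:
            raise LookupError_(f"unknown goal {code!r}; goal set is {list(self.goals)}")

    def label(self, goal: str) -> str:
        code = normalize_goal_id(goal)
        self.index(code)
        return self.labels.get(code, code)

    def ordered_pairs(self) -> list[tuple[str, str]]:
        """All ordered pairs of distinct goals, row-major."""
        return [(g, j) for g in self.goals for j in self.goals if g != j]


_SDG_LABELS = {
    1: "No poverty",
    2: "Zero hunger",
    3: "Good health and well-being",
    4: "Quality education",
    5: "Gender equality",
    6: "Clean water and sanitation",
    7: "Affordable and clean energy",
    8: "Decent work and economic growth",
    9: "Industry, innovation and infrastructure",
    10: "Reduced inequalities",
    11: "Sustainable cities and communities",
    12: "Responsible consumption and production",
    13: "Climate action",
    14: "Life below water",
    15: "Life on land",
    16: "Peace, justice and strong institutions",
    17: "Partnerships for the goals",
}


@dataclass(frozen=True)
class ScoreRecord:
    """One scored ordered goal pair with provenance.

    ``stage`` distinguishes the workflow step that produced the score:
    ``initial`` (scoring group), ``review`` (cross-reviewing group) or
    ``final`` (after discrepancy resolution).
    """

    source: str
    target: str
    score: int
    motivation: str = ""
    group: str = ""
    stage: str = "final"

    def __post_init__(self):
        object.__setattr__(self, "source", normalize_goal_id(self.source))
        object.__setattr__(self, "target", normalize_goal_id(self.target))
        if self.source == self.target:
            raise ValidationError(
                f"self-interaction {self.source}->{self.target} cannot be scored"
            )
        object.__setattr__(self, "score", _validate_score(self.score))
        if self.stage not in STAGES:
            raise ValidationError(
                f"stage must be one of {STAGES}, got {self.stage!r}"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


class CrossImpactMatrix:
    """G×G signed integer weight matrix over a :class:`GoalSet`.

    Invariants enforced at construction: integer entries in [−3, +3],
    exactly-zero diagonal.
    """

    def __init__(self, goal_set: GoalSet, weights):
        w = np.asarray(weights)
        G = len(goal_set)
        if w.shape != (G, G):
            raise ValidationError(f"weights must be {G}x{G}, got {w.shape}")
        if not np.issubdtype(w.dtype, np.integer):
            if not np.all(np.equal(np.mod(w, 1), 0)):
                raise ValidationError("weights must be integers (seven-point scale)")
            w = w.astype(np.int64)
        else:
            w = w.astype(np.int64)
        if np.any(np.diag(w) != 0):
            bad = [goal_set.goals[i] for i in np.nonzero(np.diag(w))[0]]
            raise ValidationError(f"diagonal must be zero, nonzero at {bad}")
        if w.min() < SCORE_MIN or w.max() > SCORE_MAX:
            raise ValidationError(
                f"weights outside [{SCORE_MIN}, {SCORE_MAX}]: "
                f"range [{w.min()}, {w.max()}]"
            )
        self.goal_set = goal_set
        self._w = w
        self._w.setflags(write=False)

    @property
    def weights(self) -> np.ndarray:
        """Read-only G×G int64 array; rows influence, columns are influenced."""
        return self._w

    @property
    def n_goals(self) -> int:
        return len(self.goal_set)

    def __getitem__(self, pair: tuple[str, str]) -> int:
        g, j = pair
        return int(self._w[self.goal_set.index(g), self.goal_set.index(j)])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CrossImpactMatrix):
            return NotImplemented
        return (
            self.goal_set.goals == other.goal_set.goals
            and np.array_equal(self._w, other._w)
        )

    def __repr__(self) -> str:
        return f"CrossImpactMatrix(G={self.n_goals})"

    def to_records(self, stage: str = "final") -> list[ScoreRecord]:
        """Flatten to one :class:`ScoreRecord` per ordered off-diagonal pair."""
        return [
            ScoreRecord(g, j, self[g, j], stage=stage)
            for g, j in self.goal_set.ordered_pairs()
        ]

    def permuted(self, order: Sequence[str]) -> "CrossImpactMatrix":
        """Return the matrix re-indexed to a new goal order (same goals)."""
        new_set = GoalSet(order, self.goal_set.labels)
        if set(new_set.goals) != set(self.goal_set.goals):
            raise ValidationError("permuted order must contain exactly the same goals")
        idx = [self.goal_set.index(g) for g in new_set.goals]
        return CrossImpactMatrix(new_set, self._w[np.ix_(idx, idx)])


def count_pairs(goal_set: GoalSet) -> int:
    """Number of unique ordered off-diagonal pairs, ``G·(G−1)``.

    For the default 16-goal configuration this is 240.
    """
    G = len(goal_set)
    return G * (G - 1)


def assemble_matrix(
    records: Iterable[ScoreRecord], goal_set: GoalSet
) -> CrossImpactMatrix:
    """Build the cross-impact matrix from a complete set of final scores.

    Every ordered pair of distinct goals must appear exactly once among
    ``records`` (stage ``final``); a missing pair raises
    :class:`IncompleteMatrixError`, duplicated pairs with conflicting
    scores raise :class:`ConflictError`.
    """
    G = len(goal_set)
    w = np.zeros((G, G), dtype=np.int64)
    seen: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.stage != "final":
            raise ValidationError(
                f"assemble_matrix expects stage='final' records, got "
                f"{rec.stage!r} for {rec.source}->{rec.target}"
            )
        i = goal_set.index(rec.source)
        j = goal_set.index(rec.target)
        if rec.pair in seen:
            if seen[rec.pair] != rec.score:
                raise ConflictError(
                    f"conflicting final scores for {rec.source}->{rec.target}: "
                    f"{seen[rec.pair]} vs {rec.score}"
                )
            continue
        seen[rec.pair] = rec.score
        w[i, j] = rec.score
    missing = [p for p in goal_set.ordered_pairs() if p not in seen]
    if missing:
        raise IncompleteMatrixError(missing)
    return CrossImpactMatrix(goal_set, w)


def classify_interactions(matrix: CrossImpactMatrix) -> tuple[int, int, int]:
    """Count (restricting, no_influence, promoting) off-diagonal interactions.

    Restricting means a negative weight, promoting a positive one; the
    triple always sums to ``G·(G−1)``.
    """
    w = matrix.weights
    off = ~np.eye(matrix.n_goals, dtype=bool)
    vals = w[off]
    return (
        int(np.sum(vals < 0)),
        int(np.sum(vals == 0)),
        int(np.sum(vals > 0)),
    )
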