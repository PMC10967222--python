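"""Participatory scoring workflow: cross-review, discrepancies, resolution.

The workflow this module models is the one used in SDG Synergies
workshops: each group scores a subset of ordered goal pairs (stage
``initial``), a different group re-scores the same pairs (stage
``review``), disagreements become discrepancies, and each discrepancy is
settled in plenary either by consensus or — failing that — by a vote.
Only once every discrepancy is resolved can the final score set, and
hence the cross-impact matrix, be assembled.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .errors import (
    CoverageError,
    UnresolvedDiscrepancyError,
    UnresolvedTieError,
    ValidationError,
)
from .model import SCORE_MAX, SCORE_MIN, ScoreRecord

RESOLUTION_METHODS = ("consensus", "vote", "unresolved")


@dataclass(frozen=True)
class DiscrepancyRecord:
    """A pair on which the scoring and reviewing groups disagree."""

    source: str
    target: str
    scorer_group: str
    scorer_score: int
    reviewer_group: str
    reviewer_score: int
    resolution_method: str = "unresolved"
    final_score: int | None = None

    def __post_init__(self):
        if self.scorer_score == self.reviewer_score:
            raise ValidationError(
                f"{self.source}->{self.target}: equal scores "
                f"({self.scorer_score}) are not a discrepancy"
            )
        if self.resolution_method not in RESOLUTION_METHODS:
            raise ValidationError(
                f"resolution_method must be one of {RESOLUTION_METHODS}"
            )
        resolved = self.resolution_method != "unresolved"
        if resolved != (self.final_score is not None):
            raise ValidationError(
                "final_score must be present exactly when the discrepancy "
                "is resolved"
            )

    @property
    def pair(self) -> tuple[str, str]:
        return (self.source, self.target)


@dataclass(frozen=True)
class VoteBallot:
    """Scores cast by voting units (participants or groups) on one pair."""

    pair: tuple[str, str]
    votes: tuple[int, ...]

    def __post_init__(self):
        if not self.votes:
            raise ValidationError("a ballot needs at least one vote")
        for v in self.votes:
            if not isinstance(v, int) or not SCORE_MIN <= v <= SCORE_MAX:
                raise ValidationError(f"vote {v!r} outside the seven-point scale")


def _index_by_pair(records: Iterable[ScoreRecord], stage: str) -> dict:
    out: dict[tuple[str, str], ScoreRecord] = {}
    for rec in records:
        if rec.stage != stage:
            raise ValidationError(
                f"expected stage={stage!r} records, got {rec.stage!r} "
                f"for {rec.source}->{rec.target}"
            )
        if rec.pair in out:
            raise ValidationError(
                f"duplicate {stage} score for {rec.source}->{rec.target}"
            )
        out[rec.pair] = rec
    return out


def detect_discrepancies(
    initial: Iterable[ScoreRecord], review: Iterable[ScoreRecord]
) -> list[DiscrepancyRecord]:
    """Pairs where the reviewing group disagrees with the scoring group.

    Both collections must cover exactly the same ordered pairs with one
    score each; otherwise a :class:`CoverageError` is raised.  Pairs with
    equal scores are not reported.
    """
    ini = _index_by_pair(initial, "initial")
    rev = _index_by_pair(review, "review")
    only_ini = sorted(set(ini) - set(rev))
    only_rev = sorted(set(rev) - set(ini))
    if only_ini or only_rev:
        raise CoverageError(
            f"stages cover different pairs; initial-only={only_ini[:5]}, "
            f"review-only={only_rev[:5]}"
        )
    out = []
    for pair in ini:  # insertion order = input order
        a, b = ini[pair], rev[pair]
        if a.score != b.score:
            out.append(
                DiscrepancyRecord(
                    source=pair[0],
                    target=pair[1],
                    scorer_group=a.group,
                    scorer_score=a.score,
                    reviewer_group=b.group,
                    reviewer_score=b.score,
                )
            )
    return out


def resolve_by_consensus(
    record: DiscrepancyRecord, agreed_score: int
) -> DiscrepancyRecord:
    """Settle a discrepancy with a plenary consensus score.

    The consensus need not equal either group's score — the plenary may
    settle on a compromise value anywhere on the scale.
    """
    if not isinstance(agreed_score, int) or not SCORE_MIN <= agreed_score <= SCORE_MAX:
        raise ValidationError(
            f"consensus score {agreed_score!r} outside the seven-point scale"
        )
    return replace(record, resolution_method="consensus", final_score=agreed_score)


def resolve_by_vote(record: DiscrepancyRecord, ballot: VoteBallot) -> DiscrepancyRecord:
    """Settle a discrepancy by plurality vote.

    The most common score wins.  An exact plurality tie raises
    :class:`UnresolvedTieError` — a tie means there is no majority view,
    and the case must go back to plenary discussion rather than be
    tie-broken silently.
    """
    if ballot.pair != record.pair:
        raise ValidationError(
            f"ballot is for {ballot.pair}, record is for {record.pair}"
        )
    counts = Counter(ballot.votes)
    top = counts.most_common()
    best = top[0][1]
    winners = [score for score, n in top if n == best]
    if len(winners) > 1:
        raise UnresolvedTieError(record.pair, winners)
    return replace(record, resolution_method="vote", final_score=winners[0])


def finalize_scores(
    initial: Iterable[ScoreRecord],
    review: Iterable[ScoreRecord],
    resolutions: Iterable[DiscrepancyRecord] = (),
) -> list[ScoreRecord]:
    """Produce one stage-``final`` record per ordered pair.

    Where the two stages agree the shared score is final; where they
    differ, the matching resolved :class:`DiscrepancyRecord` supplies the
    final score.  Any discrepancy without a resolution raises
    :class:`UnresolvedDiscrepancyError` listing the open pairs.
    """
    ini = _index_by_pair(initial, "initial")
    discrepancies = detect_discrepancies(ini.values(), review)
    res_by_pair: dict[tuple[str, str], DiscrepancyRecord] = {}
    for r in resolutions:
        if r.pair in res_by_pair:
            raise ValidationError(f"duplicate resolution for {r.pair}")
        res_by_pair[r.pair] = r
    open_pairs = [
        d.pair
        for d in discrepancies
        if d.pair not in res_by_pair
        or res_by_pair[d.pair].resolution_method == "unresolved"
    ]
    if open_pairs:
        raise UnresolvedDiscrepancyError(open_pairs)
    discrepant = {d.pair for d in discrepancies}
    out = []
    for pair, rec in ini.items():
        if pair in discrepant:
            res = res_by_pair[pair]
            out.append(
                ScoreRecord(
                    source=pair[0],
                    target=pair[1],
                    score=res.final_score,
                    motivation=rec.motivation,
                    group=rec.group,
                    stage="final",
                )
            )
        else:
            out.append(replace(rec, stage="final"))
    return out
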