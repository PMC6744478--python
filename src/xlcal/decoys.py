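"""Decoy ranking by crosslink-restraint satisfaction and the consistency verdict.

Docking produces many candidate complex models; the one whose restrained
lysine–lysine distances are collectively smallest is selected ("minimal
distances" read as minimal SUM of restrained distances — scale-continuous,
unlike a satisfied-restraint count; the mean is available as an alternative
key). The consistency verdict is the artifact handed back to the external
modelling round: PASS when every evaluated restraint is within tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .restraints import (
    DistanceRestraint,
    RestraintPolicy,
    RestraintReport,
    evaluate_restraints,
    summarize,
)
from .structure import StructureModel

__all__ = ["DecoyScore", "ConsistencyReport", "rank_decoys", "consistency_report"]


@dataclass
class DecoyScore:
    model_id: str
    sum_distances: float
    mean_distance: float
    n_violations: int
    max_violation: float
    n_missing: int
    rank: int = 0


@dataclass
class ConsistencyReport:
    passed: bool
    tolerance: float
    violated: list[RestraintReport]
    summary: object


def rank_decoys(
    models: Sequence[StructureModel],
    restraints: Sequence[DistanceRestraint],
    policy: RestraintPolicy = RestraintPolicy(),
    key: str = "sum",
) -> list[DecoyScore]:
    """Score and rank candidate models; rank 1 is the selected model.

    Primary key: ascending sum (or mean, ``key="mean"``) of restrained
    distances over evaluated restraints. Ties break on fewer violations,
    then smaller max violation, then input order. Models with any restraint
    unevaluable (missing atoms) are ranked after fully-evaluated ones — such
    models are deprioritized, not disqualified, since predicted models may
    truncate side chains.
    """
    if not models:
        raise ValueError("rank_decoys requires at least one model")
    if key not in {"sum", "mean"}:
        raise ValueError(f"unknown ranking key {key!r}")
    scores = []
    for idx, model in enumerate(models):
        s = summarize(evaluate_restraints(model, restraints, policy))
        mean = s.sum_distances / s.n_evaluated if s.n_evaluated else float("inf")
        scores.append(
            (
                DecoyScore(
                    model_id=model.model_id,
                    sum_distances=s.sum_distances,
                    mean_distance=mean,
                    n_violations=s.n_evaluated - s.n_satisfied,
                    max_violation=s.max_violation,
                    n_missing=s.n_total - s.n_evaluated,
                ),
                idx,
            )
        )
    primary = (lambda sc: sc.sum_distances) if key == "sum" else (lambda sc: sc.mean_distance)
    scores.sort(
        key=lambda t: (
            t[0].n_missing > 0,
            primary(t[0]),
            t[0].n_violations,
            t[0].max_violation,
            t[1],
        )
    )
    ranked = []
    for rank, (score, _) in enumerate(scores, start=1):
        score.rank = rank
        ranked.append(score)
    return ranked


def consistency_report(
    model: StructureModel,
    restraints: Sequence[DistanceRestraint],
    policy: RestraintPolicy = RestraintPolicy(),
    tolerance: float = 0.0,
) -> ConsistencyReport:
    """PASS iff every evaluated restraint has violation <= tolerance (Å).

    FAIL lists the violated restraints sorted by violation, largest first.
    """
    reports = evaluate_restraints(model, restraints, policy)
    violated = sorted(
        (r for r in reports if r.distance is not None and r.violation > tolerance),
        key=lambda r: -r.violation,
    )
    return ConsistencyReport(
        passed=not violated,
        tolerance=tolerance,
        violated=violated,
        summary=summarize(reports),
    )
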