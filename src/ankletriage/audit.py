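"""Brute-force rule-base audit: completeness, overlap, and a reference oracle.

Every diagnostic rule condition factors through the six diagnostic group
aggregates, so the whole diagnostic rule space is covered by the 2^6 = 64
total assignments of {positive, absent} to those groups. This module
enumerates them with its own literal two-valued evaluator — deliberately
independent of the inference engine's Kleene machinery — to report gaps
(assignments firing no rule), overlaps (assignments firing several), and
the priority-resolved verdict for each assignment.

``canonical_answers`` builds, for any assignment, a deterministic
complete answer set realizing it, which lets the engine be checked
against the oracle end to end.
"""

from __future__ import annotations

from itertools import product
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field

from .answers import AnswerSet
from .kb import And, AnyPositive, ConditionExpr, KnowledgeBase, NonePositive, condition_groups

__all__ = [
    "FindingAssignment",
    "AuditReport",
    "diagnostic_group_ids",
    "brute_force_classify",
    "audit_rules",
    "canonical_answers",
    "enumerate_assignments",
]

FindingAssignment = dict[str, bool]  # group id -> positive finding present?

# BMI inputs used by canonical answer sets: 70 kg / 175 cm gives
# BMI 22.9 kg/m², safely below the default elevated threshold, so the
# body-metric questions are answered without a finding.
_CANONICAL_WEIGHT_KG = 70.0
_CANONICAL_HEIGHT_CM = 175.0


class AuditReport(BaseModel):
    model_config = ConfigDict(extra="forbid")

    gap_assignments: list[FindingAssignment] = Field(default_factory=list)
    overlap_assignments: list[tuple[FindingAssignment, list[tuple[int, int]]]] = Field(
        default_factory=list
    )
    resolution_table: list[tuple[FindingAssignment, Optional[tuple[int, int]]]] = Field(
        default_factory=list
    )

    @property
    def gap_count(self) -> int:
        return len(self.gap_assignments)

    @property
    def overlap_count(self) -> int:
        return len(self.overlap_assignments)


def diagnostic_group_ids(kb: KnowledgeBase) -> list[str]:
    """Group ids referenced by diagnostic rule conditions, in KB group order."""
    referenced: set[str] = set()
    for rule in kb.rules:
        if rule.category != "diagnostic":
            continue
        for case in rule.cases:
            referenced |= condition_groups(case.condition)
    return [g.id for g in kb.groups if g.id in referenced]


def _eval_literal(expr: ConditionExpr, assignment: FindingAssignment) -> bool:
    """Literal two-valued evaluation of a condition on a total assignment."""
    if isinstance(expr, AnyPositive):
        return assignment[expr.group]
    if isinstance(expr, NonePositive):
        return not assignment[expr.group]
    if isinstance(expr, And):
        return all(_eval_literal(a, assignment) for a in expr.args)
    return any(_eval_literal(a, assignment) for a in expr.args)


def brute_force_classify(kb: KnowledgeBase, assignment: FindingAssignment) -> set[tuple[int, int]]:
    """All diagnostic (rule, case) pairs whose condition is true on the assignment."""
    hits: set[tuple[int, int]] = set()
    for rule in kb.rules:
        if rule.category != "diagnostic":
            continue
        for case in rule.cases:
            if _eval_literal(case.condition, assignment):
                hits.add((rule.rule_id, case.case_index))
    return hits


def enumerate_assignments(kb: KnowledgeBase) -> list[FindingAssignment]:
    groups = diagnostic_group_ids(kb)
    return [dict(zip(groups, bits)) for bits in product([False, True], repeat=len(groups))]


def _resolve(kb: KnowledgeBase, hits: set[tuple[int, int]]) -> Optional[tuple[int, int]]:
    """First hit under priority order: rules by rule_priority, cases in order."""
    for rule in kb.diagnostic_rules():
        for case in rule.cases:
            if (rule.rule_id, case.case_index) in hits:
                return (rule.rule_id, case.case_index)
    return None


def audit_rules(kb: KnowledgeBase) -> AuditReport:
    """Exhaustive completeness/overlap audit over all group-finding assignments."""
    gaps: list[FindingAssignment] = []
    overlaps: list[tuple[FindingAssignment, list[tuple[int, int]]]] = []
    resolution: list[tuple[FindingAssignment, Optional[tuple[int, int]]]] = []
    for assignment in enumerate_assignments(kb):
        hits = brute_force_classify(kb, assignment)
        if not hits:
            gaps.append(assignment)
        elif len(hits) > 1:
            overlaps.append((assignment, sorted(hits)))
        resolution.append((assignment, _resolve(kb, hits)))
    return AuditReport(
        gap_assignments=gaps, overlap_assignments=overlaps, resolution_table=resolution
    )


def canonical_answers(kb: KnowledgeBase, assignment: FindingAssignment) -> AnswerSet:
    """A deterministic complete answer set realizing a finding assignment.

    Positive groups get their first applicable boolean question at its
    finding answer; every other question is answered at its non-finding
    answer, respecting polarity (an absent Ottawa group requires "yes" to
    the balance question). Groups outside the assignment (the TENS
    screen) are answered without findings. Body metrics are fixed at a
    non-elevated BMI.
    """
    answers = AnswerSet(
        sex="male", weight_kg=_CANONICAL_WEIGHT_KG, height_cm=_CANONICAL_HEIGHT_CM
    )
    responses: dict[str, str] = {}
    for group in kb.groups:
        positive = assignment.get(group.id, False)
        first_done = False
        for q in kb.group_questions(group.id):
            if q.applicability == "female-only":
                continue  # auto-resolved for the canonical (male) patient
            if q.kind == "body-metric":
                continue  # answered through the fixed body metrics
            finding_answer = "yes" if q.positive_when == "affirmative" else "no"
            neutral_answer = "no" if q.positive_when == "affirmative" else "yes"
            if positive and not first_done:
                responses[q.id] = finding_answer
                first_done = True
            else:
                responses[q.id] = neutral_answer
    return answers.model_copy(update={"responses": responses})
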