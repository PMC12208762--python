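"""Tri-state forward-chaining inference over the clinical rule base.

Group findings are evaluated from the (possibly partial) questionnaire,
rule conditions are evaluated in Kleene three-valued logic, and the
diagnostic rules are scanned in priority order. A classification is
reported as determined only when it can never be retracted: a condition
that is true (or false) on the answers given stays true (false) under
every completion of the unanswered questions, so the first case that
evaluates true — with every higher-priority case already false — is
final.

Two evaluation modes exist. Strict mode applies the printed rule
conditions literally. Compatibility mode (the ``exclude_G1_Q6_from_aggregate``
flag) removes the general red-flag question G1.Q6 from the G1 aggregate
and records an affirmative answer to it as a separate red-flag note
instead; this reproduces the published second worked example, whose
printed applied rule is inconsistent with a literal reading of the rule
table.
"""

from __future__ import annotations

from itertools import product
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

from .answers import AnswerSet
from .kb import (
    And,
    AnyPositive,
    ConditionExpr,
    KnowledgeBase,
    NonePositive,
    Or,
    Question,
    condition_groups,
)
from .logic import Tri, from_bool, tri_and, tri_not, tri_or

__all__ = [
    "GroupFinding",
    "DerivedFacts",
    "TraceEntry",
    "Classification",
    "CastEligibility",
    "UnknownQuestionError",
    "EXCLUDE_G1_Q6_FLAG",
    "RED_FLAG_QUESTION",
    "compute_bmi",
    "bmi_elevated",
    "derive_facts",
    "question_finding",
    "evaluate_group",
    "evaluate_condition",
    "classify",
    "tens_eligibility",
    "next_question",
]

EXCLUDE_G1_Q6_FLAG = "exclude_G1_Q6_from_aggregate"
RED_FLAG_QUESTION = "G1.Q6"

CastEligibility = Literal["cast-allowed", "cast-prohibited", "undetermined"]


class UnknownQuestionError(ValueError):
    """An answer set references a question id the knowledge base does not define."""

    def __init__(self, question_ids: list[str]):
        self.question_ids = question_ids
        super().__init__(f"unknown question id(s): {', '.join(question_ids)}")


class GroupFinding(BaseModel):
    """Tri-state aggregate of one question group.

    positive-present: at least one applicable question has its positive
    clinical finding (short-circuits over unanswered questions).
    absent: every applicable question is answered and none is positive.
    undetermined: otherwise.
    """

    model_config = ConfigDict(extra="forbid")

    group_id: str
    state: Literal["positive-present", "absent", "undetermined"]
    contributing: list[str] = Field(default_factory=list)


class DerivedFacts(BaseModel):
    model_config = ConfigDict(extra="forbid")

    bmi: Optional[float] = None
    bmi_elevated: Optional[bool] = None


class TraceEntry(BaseModel):
    model_config = ConfigDict(extra="forbid")

    rule_id: int
    case_index: int
    leaf: str
    value: Literal["true", "false", "unknown"]


class Classification(BaseModel):
    """Outcome of the diagnostic scan.

    When ``status`` is determined the cited case's condition evaluates
    true and every higher-priority case is false; ``rule_id`` is None
    only in the degenerate determined case where a complete answer set
    matches no diagnostic rule (impossible for the bundled rule base,
    whose audit shows zero gaps). When more answers are needed,
    ``blocking`` lists the condition leaves that are still unknown.
    """

    model_config = ConfigDict(extra="forbid")

    status: Literal["determined", "needs-more-answers"]
    rule_id: Optional[int] = None
    case_index: Optional[int] = None
    outcome_label: Optional[str] = None
    trace: list[TraceEntry] = Field(default_factory=list)
    blocking: list[str] = Field(default_factory=list)
    notes: list[str] = Field(default_factory=list)
    compatibility_mode: bool = False


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m², from weight in kg and height in cm."""
    if weight_kg <= 0:
        raise ValueError(f"weight_kg must be positive, got {weight_kg}")
    if height_cm <= 0:
        raise ValueError(f"height_cm must be positive, got {height_cm}")
    return weight_kg / (height_cm / 100.0) ** 2


def bmi_elevated(bmi: float, threshold: float) -> bool:
    """Inclusive comparison: a BMI exactly at the threshold counts as elevated."""
    return bmi >= threshold


def derive_facts(kb: KnowledgeBase, answers: AnswerSet) -> DerivedFacts:
    if answers.weight_kg is None or answers.height_cm is None:
        return DerivedFacts()
    bmi = compute_bmi(answers.weight_kg, answers.height_cm)
    return DerivedFacts(bmi=bmi, bmi_elevated=bmi_elevated(bmi, kb.settings.bmi_elevated_threshold))


def _applicable(question: Question, answers: AnswerSet) -> bool:
    return question.applicability != "female-only" or answers.sex == "female"


def question_finding(kb: KnowledgeBase, answers: AnswerSet, question: Question) -> Tri:
    """Tri-state clinical finding for one question, respecting polarity.

    Female-only questions auto-resolve to no-finding for non-female
    patients. Body-metric questions contribute the thresholded BMI, or
    unknown while weight/height are missing.
    """
    if not _applicable(question, answers):
        return Tri.FALSE
    if question.kind == "body-metric":
        facts = derive_facts(kb, answers)
        if facts.bmi_elevated is None:
            return Tri.UNKNOWN
        return from_bool(facts.bmi_elevated)
    response = answers.response(question.id)
    if response is None:
        return Tri.UNKNOWN
    positive_response = "yes" if question.positive_when == "affirmative" else "no"
    return from_bool(response == positive_response)


def _aggregate_questions(kb: KnowledgeBase, group_id: str) -> list[Question]:
    questions = kb.group_questions(group_id)
    if group_id == "G1" and kb.flag(EXCLUDE_G1_Q6_FLAG):
        questions = [q for q in questions if q.id != RED_FLAG_QUESTION]
    return questions


def evaluate_group(kb: KnowledgeBase, answers: AnswerSet, group_id: str) -> GroupFinding:
    """Aggregate a group to positive-present / absent / undetermined.

    One positive finding short-circuits to positive-present regardless of
    unanswered questions; absent requires every applicable question
    answered without a finding.
    """
    kb.group(group_id)  # raises KeyError for unknown groups
    positives: list[str] = []
    unanswered: list[str] = []
    answered: list[str] = []
    for q in _aggregate_questions(kb, group_id):
        value = question_finding(kb, answers, q)
        if value is Tri.TRUE:
            positives.append(q.id)
        elif value is Tri.UNKNOWN:
            unanswered.append(q.id)
        else:
            answered.append(q.id)
    if positives:
        return GroupFinding(group_id=group_id, state="positive-present", contributing=positives)
    if unanswered:
        return GroupFinding(group_id=group_id, state="undetermined", contributing=unanswered)
    return GroupFinding(group_id=group_id, state="absent", contributing=answered)


def _leaf_value(expr: AnyPositive | NonePositive, findings: dict[str, GroupFinding]) -> Tri:
    if expr.group not in findings:
        raise KeyError(f"no finding for group {expr.group!r}")
    state = findings[expr.group].state
    if state == "positive-present":
        any_positive = Tri.TRUE
    elif state == "absent":
        any_positive = Tri.FALSE
    else:
        any_positive = Tri.UNKNOWN
    return any_positive if isinstance(expr, AnyPositive) else tri_not(any_positive)


def evaluate_condition(expr: ConditionExpr, findings: dict[str, GroupFinding]) -> Tri:
    """Kleene strong three-valued evaluation of a rule condition."""
    if isinstance(expr, (AnyPositive, NonePositive)):
        return _leaf_value(expr, findings)
    values = (evaluate_condition(arg, findings) for arg in expr.args)
    return tri_and(values) if isinstance(expr, And) else tri_or(values)


def _iter_leaves(expr: ConditionExpr):
    if isinstance(expr, (AnyPositive, NonePositive)):
        yield expr
    else:
        for arg in expr.args:
            yield from _iter_leaves(arg)


def _leaf_name(leaf: AnyPositive | NonePositive) -> str:
    return f"{leaf.op}({leaf.group})"


def _check_answers(kb: KnowledgeBase, answers: AnswerSet) -> None:
    unknown = answers.unknown_question_ids(kb)
    if unknown:
        raise UnknownQuestionError(unknown)


def _red_flag_notes(kb: KnowledgeBase, answers: AnswerSet) -> list[str]:
    if kb.flag(EXCLUDE_G1_Q6_FLAG) and answers.response(RED_FLAG_QUESTION) == "yes":
        return [
            f"red-flag: affirmative answer to {RED_FLAG_QUESTION} recorded separately "
            "and excluded from the G1 aggregate (compatibility mode)"
        ]
    return []


def _diagnostic_findings(kb: KnowledgeBase, answers: AnswerSet) -> dict[str, GroupFinding]:
    groups: set[str] = set()
    for rule in kb.diagnostic_rules():
        for case in rule.cases:
            groups |= condition_groups(case.condition)
    return {gid: evaluate_group(kb, answers, gid) for gid in sorted(groups)}


def classify(kb: KnowledgeBase, answers: AnswerSet) -> Classification:
    """Forward-chain the diagnostic rules over the answers.

    Rules are scanned in ``kb.settings.rule_priority`` order, cases in
    their declared order. The scan stops at the first case that is true
    (determined — final under any completion, because every earlier case
    is false and false/true leaf values are stable as answers accumulate)
    or at the first case that is unknown (needs-more-answers, with the
    unknown leaves reported as blocking).
    """
    _check_answers(kb, answers)
    findings = _diagnostic_findings(kb, answers)
    notes = _red_flag_notes(kb, answers)
    compat = kb.flag(EXCLUDE_G1_Q6_FLAG)
    trace: list[TraceEntry] = []
    for rule in kb.diagnostic_rules():
        for case in rule.cases:
            leaves = list(_iter_leaves(case.condition))
            for leaf in leaves:
                trace.append(
                    TraceEntry(
                        rule_id=rule.rule_id,
                        case_index=case.case_index,
                        leaf=_leaf_name(leaf),
                        value=_leaf_value(leaf, findings).value,
                    )
                )
            value = evaluate_condition(case.condition, findings)
            if value is Tri.TRUE:
                return Classification(
                    status="determined",
                    rule_id=rule.rule_id,
                    case_index=case.case_index,
                    outcome_label=rule.outcome_label,
                    trace=trace,
                    notes=notes,
                    compatibility_mode=compat,
                )
            if value is Tri.UNKNOWN:
                blocking = [
                    _leaf_name(leaf)
                    for leaf in leaves
                    if _leaf_value(leaf, findings) is Tri.UNKNOWN
                ]
                return Classification(
                    status="needs-more-answers",
                    trace=trace,
                    blocking=blocking,
                    notes=notes,
                    compatibility_mode=compat,
                )
    # complete evaluation, no case fired: a gap in the rule base
    return Classification(
        status="determined", trace=trace, notes=notes, compatibility_mode=compat
    )


def tens_eligibility(kb: KnowledgeBase, answers: AnswerSet) -> CastEligibility:
    """Cast/TENS screening from the device-eligibility rules (group G5).

    Prohibited as soon as any contraindication is present; allowed only
    once every applicable screening question is answered negative.
    """
    _check_answers(kb, answers)
    findings: dict[str, GroupFinding] = {}
    for rule in kb.eligibility_rules():
        for case in rule.cases:
            for gid in condition_groups(case.condition):
                if gid not in findings:
                    findings[gid] = evaluate_group(kb, answers, gid)
            if evaluate_condition(case.condition, findings) is Tri.TRUE:
                return (
                    "cast-prohibited"
                    if rule.outcome_label == "The patient cannot use the cast"
                    else "cast-allowed"
                )
    return "undetermined"


def _eval_bool(expr: ConditionExpr, positive: dict[str, bool]) -> bool:
    # two-valued evaluation used only for the relevance scan on
    # hypothetical completions of the undetermined groups
    if isinstance(expr, AnyPositive):
        return positive[expr.group]
    if isinstance(expr, NonePositive):
        return not positive[expr.group]
    if isinstance(expr, And):
        return all(_eval_bool(a, positive) for a in expr.args)
    return any(_eval_bool(a, positive) for a in expr.args)


def _resolved_case(kb: KnowledgeBase, positive: dict[str, bool]) -> Optional[tuple[int, int]]:
    for rule in kb.diagnostic_rules():
        for case in rule.cases:
            if _eval_bool(case.condition, positive):
                return (rule.rule_id, case.case_index)
    return None


def _relevant_diagnostic_groups(
    kb: KnowledgeBase, findings: dict[str, GroupFinding]
) -> set[str]:
    """Undetermined groups whose resolution can still change the verdict.

    Enumerates every completion of the undetermined groups (each group
    independently positive or absent) and keeps a group iff flipping it,
    with all other groups held fixed, changes the priority-resolved
    (rule, case) for at least one completion.
    """
    undecided = sorted(g for g, f in findings.items() if f.state == "undetermined")
    fixed = {g: f.state == "positive-present" for g, f in findings.items() if f.state != "undetermined"}
    relevant: set[str] = set()
    for bits in product([False, True], repeat=len(undecided)):
        assignment = dict(fixed, **dict(zip(undecided, bits)))
        base = _resolved_case(kb, assignment)
        for g in undecided:
            if g in relevant:
                continue
            flipped = dict(assignment)
            flipped[g] = not flipped[g]
            if _resolved_case(kb, flipped) != base:
                relevant.add(g)
    return relevant


def next_question(kb: KnowledgeBase, answers: AnswerSet) -> Optional[str]:
    """The next question worth asking, or None when nothing can change.

    Questions are offered in the KB's declared group order, questions in
    declared order, skipping groups whose finding is already fixed and
    groups that cannot alter the still-undetermined part of the
    (classification, eligibility) pair. Returns None when both are
    determined.
    """
    classification = classify(kb, answers)
    eligibility = tens_eligibility(kb, answers)

    relevant: set[str] = set()
    if classification.status == "needs-more-answers":
        findings = _diagnostic_findings(kb, answers)
        relevant |= _relevant_diagnostic_groups(kb, findings)
    if eligibility == "undetermined":
        for rule in kb.eligibility_rules():
            for case in rule.cases:
                for gid in condition_groups(case.condition):
                    if evaluate_group(kb, answers, gid).state == "undetermined":
                        relevant.add(gid)

    for group in kb.groups:
        if group.id not in relevant:
            continue
        for q in _aggregate_questions(kb, group.id):
            if not _applicable(q, answers):
                continue
            if question_finding(kb, answers, q) is Tri.UNKNOWN:
                return q.id
    return None
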