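"""Declarative clinical knowledge base: schema, loading, validation, serialization.

The knowledge base is a versioned document holding question groups,
polarity-aware questions, IF-THEN rules whose conditions are boolean
expressions over group-level aggregates, and injury recovery plans.
The bundled fixture encodes the published ankle-injury triage rule set
built on the Ottawa Ankle Rules: five rules (three diagnostic, two
cast/TENS eligibility) over seven question groups and 32 questions.

Documents are JSON (canonical) or YAML (accepted). All structural
constraints are enforced by pydantic models at load time; content
invariants that cut across objects (dangling references, empty groups,
duplicate identifiers) are reported by :func:`validate_kb` as issue
records rather than exceptions, so a partially broken document can be
diagnosed in one pass.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Annotated, Literal, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

__all__ = [
    "Question",
    "QuestionGroup",
    "AnyPositive",
    "NonePositive",
    "And",
    "Or",
    "ConditionExpr",
    "RuleCase",
    "Rule",
    "PlanPhase",
    "RecoveryPlan",
    "Settings",
    "KnowledgeBase",
    "Issue",
    "KBLoadError",
    "load_kb",
    "loads_kb",
    "validate_kb",
    "serialize_kb",
    "bundled_kb",
    "kb_json_schema",
]

DIAGNOSTIC_GROUPS = ("G1", "G2", "G3-A", "G3-B", "G4-A", "G4-B")
GROUP_ORDER = ("G1", "G2", "G3-A", "G3-B", "G4-A", "G4-B", "G5")


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Question(_Model):
    """A single questionnaire item.

    ``positive_when`` maps the literal answer to the clinical finding the
    question probes: most questions flag a finding on "yes", but the
    weight-bearing/balance question is inverted (inability to bear weight
    is the positive Ottawa finding), and body-metric questions flag a
    finding when the computed BMI meets the elevated threshold.
    """

    id: str
    group_id: str
    text: str
    kind: Literal["boolean", "body-metric"] = "boolean"
    positive_when: Literal["affirmative", "negative", "threshold-exceeded"] = "affirmative"
    applicability: Literal["all", "female-only"] = "all"


class QuestionGroup(_Model):
    id: str
    label: str
    role: Literal[
        "contraindication-screen",
        "ottawa-findings",
        "fracture-sign",
        "sprain-sign",
        "tens-screen",
    ]


class AnyPositive(_Model):
    """True when at least one question in the group has its positive finding."""

    op: Literal["any_positive"] = "any_positive"
    group: str


class NonePositive(_Model):
    """True when every applicable question in the group is answered without a finding."""

    op: Literal["none_positive"] = "none_positive"
    group: str


class And(_Model):
    op: Literal["and"] = "and"
    args: list["ConditionExpr"] = Field(min_length=1)


class Or(_Model):
    op: Literal["or"] = "or"
    args: list["ConditionExpr"] = Field(min_length=1)


ConditionExpr = Annotated[Union[AnyPositive, NonePositive, And, Or], Field(discriminator="op")]

And.model_rebuild()
Or.model_rebuild()


def condition_groups(expr: ConditionExpr) -> set[str]:
    """All group ids referenced by leaves of the expression tree."""
    if isinstance(expr, (AnyPositive, NonePositive)):
        return {expr.group}
    out: set[str] = set()
    for arg in expr.args:
        out |= condition_groups(arg)
    return out


class RuleCase(_Model):
    case_index: int = Field(ge=1)
    condition: ConditionExpr


class Rule(_Model):
    rule_id: int = Field(ge=1)
    name: str = ""
    category: Literal["diagnostic", "device-eligibility"]
    outcome_label: str
    cases: list[RuleCase] = Field(min_length=1)


class PlanPhase(_Model):
    week_range: str
    instruction: str


class RecoveryPlan(_Model):
    """Injury-type-keyed recovery timeline.

    ``provisional`` marks plans defined only by analogy to another injury
    type (the spiral-type fracture plan mirrors the avulsion-type one) or
    shipped with minimal content pending clinician review.
    """

    injury_key: str
    healing_duration_weeks: int = Field(gt=0)
    residual_symptom_horizon_months: int = Field(gt=0)
    provisional: bool = False
    phases: list[PlanPhase] = Field(default_factory=list)


class Settings(_Model):
    bmi_elevated_threshold: float = Field(default=25.0, gt=0)
    rule_priority: list[int] = Field(default_factory=lambda: [1, 2, 3])
    compatibility_flags: dict[str, bool] = Field(default_factory=dict)
    outcome_paths: dict[str, Literal["visit-clinician", "home-care", "no-action"]] = Field(
        default_factory=dict
    )


class KnowledgeBase(_Model):
    version: str
    groups: list[QuestionGroup]
    questions: list[Question]
    rules: list[Rule]
    recovery_plans: list[RecoveryPlan] = Field(default_factory=list)
    settings: Settings = Field(default_factory=Settings)

    @field_validator("version")
    @classmethod
    def _nonempty_version(cls, v: str) -> str:
        if not v:
            raise ValueError("version must be non-empty")
        return v

    # -- convenience lookups -------------------------------------------------

    def group(self, group_id: str) -> QuestionGroup:
        for g in self.groups:
            if g.id == group_id:
                return g
        raise KeyError(f"unknown group {group_id!r}")

    def group_questions(self, group_id: str) -> list[Question]:
        return [q for q in self.questions if q.group_id == group_id]

    def question(self, question_id: str) -> Question:
        for q in self.questions:
            if q.id == question_id:
                return q
        raise KeyError(f"unknown question {question_id!r}")

    def rule(self, rule_id: int) -> Rule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(f"unknown rule {rule_id}")

    def diagnostic_rules(self) -> list[Rule]:
        """Diagnostic rules in priority (conflict-resolution) order."""
        by_id = {r.rule_id: r for r in self.rules if r.category == "diagnostic"}
        ordered = [by_id[i] for i in self.settings.rule_priority if i in by_id]
        ordered += [r for r in by_id.values() if r.rule_id not in self.settings.rule_priority]
        return ordered

    def eligibility_rules(self) -> list[Rule]:
        return [r for r in self.rules if r.category == "device-eligibility"]

    def recovery_plan(self, injury_key: str) -> RecoveryPlan:
        for p in self.recovery_plans:
            if p.injury_key == injury_key:
                return p
        known = ", ".join(sorted(p.injury_key for p in self.recovery_plans))
        raise KeyError(f"unknown injury key {injury_key!r}; known keys: {known}")

    def flag(self, name: str) -> bool:
        return self.settings.compatibility_flags.get(name, False)


class Issue(_Model):
    severity: Literal["error", "warning"]
    location: str
    message: str


class KBLoadError(ValueError):
    """Raised when a document cannot be materialized into a valid knowledge base."""


def validate_kb(kb: KnowledgeBase) -> list[Issue]:
    """Check cross-object invariants; returns an empty list iff the KB is sound.

    Issues are data, not exceptions: every problem found is reported, each
    with a severity, a location path, and a message.
    """
    issues: list[Issue] = []

    def err(location: str, message: str) -> None:
        issues.append(Issue(severity="error", location=location, message=message))

    group_ids = [g.id for g in kb.groups]
    seen: set[str] = set()
    for g in kb.groups:
        if g.id in seen:
            err(f"groups[{g.id}]", f"duplicate group id {g.id!r}")
        seen.add(g.id)
    defined_groups = set(group_ids)

    seen_q: set[str] = set()
    for q in kb.questions:
        loc = f"questions[{q.id}]"
        if q.id in seen_q:
            err(loc, f"duplicate question id {q.id!r}")
        seen_q.add(q.id)
        if q.group_id not in defined_groups:
            err(loc, f"references undefined group {q.group_id!r}")
        if q.kind == "body-metric" and q.positive_when != "threshold-exceeded":
            err(loc, "body-metric questions must have positive_when = threshold-exceeded")
        if q.kind == "boolean" and q.positive_when == "threshold-exceeded":
            err(loc, "boolean questions cannot have positive_when = threshold-exceeded")

    questions_by_group: dict[str, int] = {}
    for q in kb.questions:
        questions_by_group[q.group_id] = questions_by_group.get(q.group_id, 0) + 1
    for g in kb.groups:
        if questions_by_group.get(g.id, 0) == 0:
            err(f"groups[{g.id}]", f"group {g.id!r} has no questions")

    seen_r: set[int] = set()
    for r in kb.rules:
        loc = f"rules[{r.rule_id}]"
        if r.rule_id in seen_r:
            err(loc, f"duplicate rule id {r.rule_id}")
        seen_r.add(r.rule_id)
        expected = list(range(1, len(r.cases) + 1))
        if [c.case_index for c in r.cases] != expected:
            err(loc, "case_index values must be consecutive starting at 1")
        for c in r.cases:
            for gid in sorted(condition_groups(c.condition)):
                if gid not in defined_groups:
                    err(f"{loc}.cases[{c.case_index}]", f"condition references undefined group {gid!r}")

    diag_ids = {r.rule_id for r in kb.rules if r.category == "diagnostic"}
    for rid in kb.settings.rule_priority:
        if rid not in diag_ids:
            err("settings.rule_priority", f"rule {rid} is not a diagnostic rule")
    missing = diag_ids - set(kb.settings.rule_priority)
    if missing:
        err("settings.rule_priority", f"diagnostic rules missing from priority order: {sorted(missing)}")

    seen_p: set[str] = set()
    for p in kb.recovery_plans:
        loc = f"recovery_plans[{p.injury_key}]"
        if p.injury_key in seen_p:
            err(loc, f"duplicate injury key {p.injury_key!r}")
        seen_p.add(p.injury_key)
        # horizon and healing compared in weeks (4 weeks per month, conservative)
        if p.residual_symptom_horizon_months * 4 < p.healing_duration_weeks:
            err(loc, "residual-symptom horizon is shorter than the healing duration")

    return issues


def loads_kb(text: str, *, fmt: Literal["json", "yaml"] = "json") -> KnowledgeBase:
    """Parse and fully validate a KB document from a string."""
    try:
        raw = yaml.safe_load(text) if fmt == "yaml" else json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise KBLoadError(f"document is not well-formed {fmt}: {exc}") from exc
    if not isinstance(raw, dict):
        raise KBLoadError("document root must be a mapping")
    try:
        kb = KnowledgeBase.model_validate(raw)
    except Exception as exc:
        raise KBLoadError(f"document does not conform to the KB schema: {exc}") from exc
    errors = [i for i in validate_kb(kb) if i.severity == "error"]
    if errors:
        detail = "; ".join(f"{i.location}: {i.message}" for i in errors)
        raise KBLoadError(f"knowledge base is invalid: {detail}")
    return kb


def load_kb(source: str | Path) -> KnowledgeBase:
    """Load a KB document from a JSON (``.json``) or YAML (``.yaml``/``.yml``) file."""
    path = Path(source)
    fmt: Literal["json", "yaml"] = "yaml" if path.suffix.lower() in {".yaml", ".yml"} else "json"
    return loads_kb(path.read_text(), fmt=fmt)


def serialize_kb(kb: KnowledgeBase, *, fmt: Literal["json", "yaml"] = "json") -> str:
    """Serialize a valid KB back to a document; load/serialize round-trips exactly."""
    errors = [i for i in validate_kb(kb) if i.severity == "error"]
    if errors:
        detail = "; ".join(f"{i.location}: {i.message}" for i in errors)
        raise KBLoadError(f"refusing to serialize an invalid knowledge base: {detail}")
    data = kb.model_dump(mode="json")
    if fmt == "yaml":
        return yaml.safe_dump(data, sort_keys=False, allow_unicode=True)
    return json.dumps(data, indent=2, ensure_ascii=False) + "\n"


@lru_cache(maxsize=1)
def _bundled() -> KnowledgeBase:
    text = resources.files("ankletriage.data").joinpath("ankle_kb.json").read_text()
    return loads_kb(text)


def bundled_kb() -> KnowledgeBase:
    """The packaged ankle-injury knowledge base (a fresh copy on every call)."""
    return _bundled().model_copy(deep=True)


def kb_json_schema() -> dict:
    """JSON Schema for KB documents, derived from the pydantic models."""
    return KnowledgeBase.model_json_schema()
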