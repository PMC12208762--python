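"""Care-path recommendation, recovery plans, TENS guidance, and follow-up logs.

The triage layer maps a determined classification onto the system's two
care paths — visit a clinician (fracture work-up: x-ray, cast, TENS
under clinician control) or home care (rest plus exercises, with remote
follow-up) — and exposes the stored recovery plans and the electrode
placement steps. Pain-score follow-up is recorded and summarised
descriptively only; an affirmative stop signal from the patient raises
an emergency-stop event for the clinician.
"""

from __future__ import annotations

from datetime import datetime
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .inference import CastEligibility, Classification
from .kb import KnowledgeBase, RecoveryPlan

__all__ = [
    "TriagePath",
    "TriageRecommendation",
    "PainReport",
    "PainLog",
    "EmergencyStopEvent",
    "PainTrend",
    "UndeterminedClassificationError",
    "recommend_path",
    "get_recovery_plan",
    "tens_placement_steps",
    "record_pain_report",
    "pain_trend",
]

TriagePath = Literal["visit-clinician", "home-care", "no-action"]

_PATH_NARRATIVE = {
    "visit-clinician": (
        "Visit a clinician for further assessment; expected procedures include "
        "x-rays, applying a cast, and clinician-administered TENS therapy."
    ),
    "home-care": (
        "Rest at home and perform the recommended exercises; remote follow-up "
        "continues through the treatment period."
    ),
    "no-action": "No injury detected; no care path is required.",
}


class UndeterminedClassificationError(ValueError):
    """Raised when a recommendation is requested before the diagnosis is determined."""

    def __init__(self, blocking: list[str]):
        self.blocking = blocking
        super().__init__(
            "classification is not determined; blocking conditions: "
            + (", ".join(blocking) or "<none reported>")
        )


class TriageRecommendation(BaseModel):
    model_config = ConfigDict(extra="forbid")

    path: TriagePath
    tens_allowed: Optional[bool] = None  # None while eligibility is undetermined
    red_flags: list[str] = Field(default_factory=list)
    narrative: str = ""


def recommend_path(
    kb: KnowledgeBase, classification: Classification, eligibility: CastEligibility
) -> TriageRecommendation:
    """Map a determined outcome onto a care path.

    The outcome-to-path mapping lives in ``kb.settings.outcome_paths`` so
    it is knowledge-base data rather than code. TENS permission is copied
    from the eligibility screen; red flags (e.g. the excluded general
    red-flag question in compatibility mode) are carried through.
    """
    if classification.status != "determined":
        raise UndeterminedClassificationError(classification.blocking)
    if classification.outcome_label is None:
        raise ValueError("classification matched no rule; no care path is defined")
    try:
        path = kb.settings.outcome_paths[classification.outcome_label]
    except KeyError:
        raise ValueError(
            f"no care path configured for outcome {classification.outcome_label!r}"
        ) from None
    tens_allowed: Optional[bool]
    if eligibility == "undetermined":
        tens_allowed = None
        tens_text = "TENS/cast eligibility is not yet determined."
    elif eligibility == "cast-allowed":
        tens_allowed = True
        tens_text = "The patient can use the cast."
    else:
        tens_allowed = False
        tens_text = "The patient cannot use the cast."
    narrative = f"{classification.outcome_label}. {_PATH_NARRATIVE[path]} {tens_text}"
    return TriageRecommendation(
        path=path,
        tens_allowed=tens_allowed,
        red_flags=list(classification.notes),
        narrative=narrative,
    )


def get_recovery_plan(kb: KnowledgeBase, injury_key: str) -> RecoveryPlan:
    """Stored recovery plan for an injury key; raises listing known keys otherwise."""
    return kb.recovery_plan(injury_key)


def tens_placement_steps() -> tuple[str, ...]:
    """Fixed electrode placement guidance (two pads near the painful area)."""
    return (
        "Clean and dry the skin around the painful area before placing the electrodes.",
        "Place the two electrode pads over or near the area of pain, following the placement guide.",
        "Attach the electrodes firmly, using adhesive if necessary.",
    )


class PainReport(BaseModel):
    """One follow-up self-report: pain score 0-10 plus device state.

    ``tens_intensity`` is an opaque ordinal device level; ``stopped``
    signals that the patient has stopped TENS therapy.
    """

    model_config = ConfigDict(extra="forbid")

    timestamp: datetime
    score: int = Field(ge=0, le=10)
    tens_intensity: Optional[int] = Field(default=None, ge=0)
    stopped: bool = False


class EmergencyStopEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    timestamp: datetime
    patient_ref: str
    triggering_report: PainReport


class PainLog(BaseModel):
    model_config = ConfigDict(extra="forbid")

    patient_ref: str = "anonymous"
    reports: list[PainReport] = Field(default_factory=list)

    def to_jsonl(self) -> str:
        return "".join(r.model_dump_json() + "\n" for r in self.reports)

    @classmethod
    def from_jsonl(cls, text: str, patient_ref: str = "anonymous") -> "PainLog":
        reports = [
            PainReport.model_validate_json(line)
            for line in text.splitlines()
            if line.strip()
        ]
        return cls(patient_ref=patient_ref, reports=reports)


def record_pain_report(
    log: PainLog, report: PainReport
) -> tuple[PainLog, Optional[EmergencyStopEvent]]:
    """Append a report to the log; emit an emergency stop iff the patient stopped.

    Reports must arrive in timestamp order (the log is totally ordered
    per patient).
    """
    if log.reports and report.timestamp < log.reports[-1].timestamp:
        raise ValueError(
            f"report timestamp {report.timestamp.isoformat()} precedes the last "
            f"logged report {log.reports[-1].timestamp.isoformat()}"
        )
    updated = log.model_copy(update={"reports": [*log.reports, report]})
    event = None
    if report.stopped:
        event = EmergencyStopEvent(
            timestamp=report.timestamp,
            patient_ref=log.patient_ref,
            triggering_report=report,
        )
    return updated, event


class PainTrend(BaseModel):
    model_config = ConfigDict(extra="forbid")

    latest_score: int
    mean_score: float
    slope_per_day: Optional[float] = None  # absent with fewer than two reports


def pain_trend(log: PainLog) -> PainTrend:
    """Descriptive summary: latest score, mean, and OLS slope in score/day."""
    if not log.reports:
        raise ValueError("pain log is empty")
    scores = np.array([r.score for r in log.reports], dtype=float)
    trend = PainTrend(latest_score=log.reports[-1].score, mean_score=float(scores.mean()))
    if len(log.reports) >= 2:
        t0 = log.reports[0].timestamp
        days = np.array(
            [(r.timestamp - t0).total_seconds() / 86400.0 for r in log.reports]
        )
        if np.ptp(days) > 0:
            slope = float(np.polyfit(days, scores, 1)[0])
            trend = trend.model_copy(update={"slope_per_day": slope})
    return trend
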