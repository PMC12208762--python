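"""Patient answer sets and their file formats (JSON and CSV)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .kb import KnowledgeBase

__all__ = [
    "AnswerSet",
    "read_answers_json",
    "write_answers_json",
    "read_answers_csv",
    "write_answers_csv",
]

Response = Literal["yes", "no"]

_META_COLUMNS = ("patient_id", "sex", "weight_kg", "height_cm")


class AnswerSet(BaseModel):
    """A patient's (possibly partial) questionnaire responses plus body metrics.

    A question id absent from ``responses`` is unanswered. Weight and
    height feed the BMI sub-computation behind the body-metric questions;
    either may be absent, in which case those questions count as
    unanswered.
    """

    model_config = ConfigDict(extra="forbid")

    sex: Literal["female", "male", "unspecified"] = "unspecified"
    responses: dict[str, Response] = Field(default_factory=dict)
    weight_kg: Optional[float] = Field(default=None, gt=0)
    height_cm: Optional[float] = Field(default=None, gt=0)

    def response(self, question_id: str) -> Optional[Response]:
        return self.responses.get(question_id)

    def unknown_question_ids(self, kb: KnowledgeBase) -> list[str]:
        """Response keys that do not name a question defined by the KB."""
        defined = {q.id for q in kb.questions}
        return sorted(set(self.responses) - defined)

    def with_response(self, question_id: str, value: Response) -> "AnswerSet":
        updated = dict(self.responses)
        updated[question_id] = value
        return self.model_copy(update={"responses": updated})


def read_answers_json(source: str | Path) -> AnswerSet:
    return AnswerSet.model_validate(json.loads(Path(source).read_text()))


def write_answers_json(answers: AnswerSet, target: str | Path) -> None:
    Path(target).write_text(json.dumps(answers.model_dump(mode="json"), indent=2) + "\n")


def _row_to_answers(row: pd.Series, question_cols: list[str]) -> AnswerSet:
    responses = {}
    for qid in question_cols:
        value = str(row[qid]).strip().lower()
        if value in ("yes", "no"):
            responses[qid] = value
        elif value not in ("", "nan"):
            raise ValueError(f"invalid response {row[qid]!r} for question {qid!r}")
    sex = str(row.get("sex", "") or "").strip().lower() or "unspecified"
    weight = row.get("weight_kg")
    height = row.get("height_cm")
    return AnswerSet(
        sex=sex,  # type: ignore[arg-type]
        responses=responses,
        weight_kg=float(weight) if weight not in (None, "") and not pd.isna(weight) else None,
        height_cm=float(height) if height not in (None, "") and not pd.isna(height) else None,
    )


def read_answers_csv(source: str | Path) -> list[AnswerSet]:
    """Read a cohort CSV: one row per patient, one column per question id.

    Recognised metadata columns: ``patient_id``, ``sex``, ``weight_kg``,
    ``height_cm``; every other column is a question id with values yes /
    no / empty (unanswered).
    """
    frame = pd.read_csv(source, dtype=str, keep_default_na=False)
    question_cols = [c for c in frame.columns if c not in _META_COLUMNS]
    return [_row_to_answers(row, question_cols) for _, row in frame.iterrows()]


def write_answers_csv(cohort: list[AnswerSet], kb: KnowledgeBase, target: str | Path) -> None:
    """Write a cohort CSV with one column per KB question, in KB order."""
    qids = [q.id for q in kb.questions]
    rows = []
    for i, a in enumerate(cohort, start=1):
        row: dict[str, object] = {
            "patient_id": i,
            "sex": a.sex,
            "weight_kg": "" if a.weight_kg is None else a.weight_kg,
            "height_cm": "" if a.height_cm is None else a.height_cm,
        }
        for qid in qids:
            row[qid] = a.responses.get(qid, "")
        rows.append(row)
    pd.DataFrame(rows, columns=list(_META_COLUMNS) + qids).to_csv(target, index=False)
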