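"""Seeded synthetic patient cohorts for testing and simulation.

Each synthetic patient is drawn independently: a sex, a per-question
Bernoulli draw for every boolean clinical finding (mapped to a literal
yes/no answer through the question's polarity), and body metrics
constructed so that the BMI lands on the intended side of the elevated
threshold. A single seeded NumPy generator drives everything, so a
(seed, config) pair reproduces its cohort exactly.

The default finding probabilities describe a plausible walk-in
population for an ankle-injury triage app — sprain signs more common
than fracture signs, contraindications rare — and are not calibrated to
any epidemiological source.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .answers import AnswerSet
from .kb import KnowledgeBase

__all__ = ["CohortConfig", "generate_cohort", "DEFAULT_GROUP_PROBABILITIES"]

# per-group default probability that any single boolean question in the
# group shows its positive finding
DEFAULT_GROUP_PROBABILITIES: dict[str, float] = {
    "G1": 0.05,
    "G2": 0.30,
    "G3-A": 0.25,
    "G3-B": 0.10,
    "G4-A": 0.35,
    "G4-B": 0.30,
    "G5": 0.05,
}

_Prob = Field(ge=0.0, le=1.0)


class CohortConfig(BaseModel):
    """Sampling configuration for one synthetic cohort."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    n: int = Field(default=100, ge=1)
    sex_ratio: float = Field(default=0.5, ge=0.0, le=1.0)  # P(female)
    group_probabilities: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_GROUP_PROBABILITIES)
    )
    question_probabilities: dict[str, float] = Field(default_factory=dict)  # overrides
    default_probability: float = Field(default=0.1, ge=0.0, le=1.0)
    p_bmi_elevated: float = Field(default=0.35, ge=0.0, le=1.0)
    height_mean_cm: float = Field(default=170.0, gt=0)
    height_sd_cm: float = Field(default=10.0, ge=0)

    def probability_for(self, question_id: str, group_id: str) -> float:
        if question_id in self.question_probabilities:
            p = self.question_probabilities[question_id]
        else:
            p = self.group_probabilities.get(group_id, self.default_probability)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"probability for {question_id!r} out of [0, 1]: {p}")
        return p

    def all_zero(self) -> "CohortConfig":
        """A copy with every positive-finding probability set to zero."""
        return self.model_copy(
            update={
                "group_probabilities": {g: 0.0 for g in self.group_probabilities},
                "question_probabilities": {q: 0.0 for q in self.question_probabilities},
                "default_probability": 0.0,
                "p_bmi_elevated": 0.0,
            }
        )


def _sample_body_metrics(
    rng: np.random.Generator, config: CohortConfig, threshold: float
) -> tuple[float, float]:
    """Height and weight with the BMI drawn on one side of the threshold.

    The elevated/non-elevated indicator is Bernoulli(p_bmi_elevated); the
    BMI magnitude is then drawn with a 0.5 kg/m² guard band around the
    threshold so rounding the weight cannot flip the side.
    """
    height = float(np.clip(rng.normal(config.height_mean_cm, config.height_sd_cm), 140.0, 210.0))
    if rng.random() < config.p_bmi_elevated:
        bmi = threshold + 0.5 + abs(rng.normal(0.0, 3.0))
    else:
        bmi = max(16.0, threshold - 0.5 - abs(rng.normal(0.0, 2.5)))
    weight = round(bmi * (height / 100.0) ** 2, 1)
    return weight, round(height, 1)


def _sample_patient(
    rng: np.random.Generator, kb: KnowledgeBase, config: CohortConfig
) -> AnswerSet:
    sex = "female" if rng.random() < config.sex_ratio else "male"
    weight, height = _sample_body_metrics(rng, config, kb.settings.bmi_elevated_threshold)
    responses: dict[str, str] = {}
    for q in kb.questions:
        if q.kind == "body-metric":
            continue  # realized through weight/height
        if q.applicability == "female-only" and sex != "female":
            continue  # pregnancy questions sampled only for female records
        finding = rng.random() < config.probability_for(q.id, q.group_id)
        if q.positive_when == "affirmative":
            responses[q.id] = "yes" if finding else "no"
        else:
            responses[q.id] = "no" if finding else "yes"
    return AnswerSet(sex=sex, responses=responses, weight_kg=weight, height_cm=height)


def generate_cohort(kb: KnowledgeBase, config: Optional[CohortConfig] = None) -> list[AnswerSet]:
    """Draw ``config.n`` independent complete answer sets; reproducible by seed."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    return [_sample_patient(rng, kb, config) for _ in range(config.n)]
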