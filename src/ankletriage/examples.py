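"""The two published worked-example patients, transcribed answer for answer.

Patient 1 presents with positive Ottawa findings and multiple fracture
signs and is classified Rule 1 Case 1 (high possibility of ankle
fracture). Patient 2 answers the general red-flag question (G1.Q6)
affirmatively yet was published with applied rule "Rule 2: Case 1"
(ankle sprain), which a literal reading of the rule table contradicts —
see the compatibility mode in :mod:`ankletriage.inference`.

Neither patient supplied weight/height, so the body-metric questions
are unanswered, and neither answered the TENS screening group.
"""

from __future__ import annotations

from .answers import AnswerSet

__all__ = ["patient_one", "patient_two"]


def patient_one() -> AnswerSet:
    return AnswerSet(
        responses={
            "G1.Q1": "no",
            "G1.Q2": "no",
            "G1.Q3": "no",
            "G1.Q4": "no",
            "G1.Q5": "no",
            "G1.Q6": "no",
            "G2.Q1": "yes",
            "G2.Q2": "yes",
            "G2.Q3": "no",
            "G3-A.Q1": "yes",
            "G3-A.Q2": "yes",
            "G3-A.Q3": "yes",
            "G3-B.Q4": "yes",
            "G3-B.Q5": "no",
            "G3-B.Q6": "yes",
            "G3-B.Q7": "no",
            "G3-B.Q9": "yes",
        }
    )


def patient_two() -> AnswerSet:
    return AnswerSet(
        responses={
            "G1.Q1": "no",
            "G1.Q2": "no",
            "G1.Q3": "no",
            "G1.Q4": "no",
            "G1.Q5": "no",
            "G1.Q6": "yes",
            "G2.Q1": "no",
            "G2.Q2": "no",
            "G2.Q3": "yes",
            "G3-A.Q1": "yes",
            "G3-A.Q2": "no",
            "G3-A.Q3": "no",
            "G3-B.Q4": "no",
            "G3-B.Q5": "no",
            "G3-B.Q6": "no",
            "G3-B.Q7": "no",
            "G3-B.Q9": "no",
            "G4-A.Q1": "yes",
            "G4-A.Q2": "yes",
            "G4-A.Q3": "yes",
            "G4-B.Q1": "yes",
            "G4-B.Q2": "yes",
            "G4-B.Q3": "yes",
        }
    )
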