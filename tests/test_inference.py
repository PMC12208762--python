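"""Tri-state evaluation, forward chaining, eligibility, and question sequencing."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ankletriage import (
    AnswerSet,
    UnknownQuestionError,
    bmi_elevated,
    classify,
    compute_bmi,
    evaluate_condition,
    evaluate_group,
    next_question,
    tens_eligibility,
)
from ankletriage.audit import canonical_answers, enumerate_assignments
from ankletriage.inference import GroupFinding, derive_facts
from ankletriage.kb import And, AnyPositive, NonePositive, Or
from ankletriage.logic import Tri


def _all_negative(kb, sex="male"):
    """Complete answer set with every finding absent (polarity-aware)."""
    return canonical_answers(kb, {g: False for g in ("G1", "G2", "G3-A", "G3-B", "G4-A", "G4-B")})


class TestBmi:
    @pytest.mark.parametrize(
        "weight,height,expected",
        [(70, 175, 22.857142857142858), (100, 100, 100.0), (80, 200, 20.0)],
    )
    def test_compute_bmi(self, weight, height, expected):
        assert compute_bmi(weight, height) == pytest.approx(expected)

    @pytest.mark.parametrize("weight,height", [(80, 0), (0, 175), (-5, 170)])
    def test_non_positive_inputs_rejected(self, weight, height):
        with pytest.raises(ValueError):
            compute_bmi(weight, height)

    def test_threshold_is_inclusive(self):
        assert bmi_elevated(26.0, 25.0)
        assert bmi_elevated(25.0, 25.0)  # boundary counts as elevated
        assert not bmi_elevated(20.0, 25.0)

    def test_derived_facts_require_both_metrics(self, kb):
        assert derive_facts(kb, AnswerSet(weight_kg=70)).bmi is None
        facts = derive_facts(kb, AnswerSet(weight_kg=70, height_cm=175))
        assert facts.bmi == pytest.approx(22.857142857142858)
        assert facts.bmi_elevated is False


class TestEvaluateGroup:
    def test_patient1_g1_all_no_is_absent(self, kb, p1):
        assert evaluate_group(kb, p1, "G1").state == "absent"

    def test_patient2_g2_absent_under_inverted_polarity(self, kb, p2):
        """'Yes, able to balance' is not an Ottawa finding, so G2 is absent."""
        assert evaluate_group(kb, p2, "G2").state == "absent"

    def test_one_positive_short_circuits_unanswered(self, kb):
        answers = AnswerSet(responses={"G3-A.Q1": "yes"})
        finding = evaluate_group(kb, answers, "G3-A")
        assert finding.state == "positive-present"
        assert finding.contributing == ["G3-A.Q1"]

    def test_partial_negatives_stay_undetermined(self, kb):
        answers = AnswerSet(responses={"G3-A.Q1": "no"})
        assert evaluate_group(kb, answers, "G3-A").state == "undetermined"

    def test_body_metric_contributes_thresholded_value(self, kb):
        heavy = AnswerSet(
            weight_kg=100,
            height_cm=170,
            responses={f"G3-B.Q{i}": "no" for i in (4, 5, 6, 7, 9)},
        )
        assert evaluate_group(kb, heavy, "G3-B").state == "positive-present"
        light = heavy.model_copy(update={"weight_kg": 60.0})
        assert evaluate_group(kb, light, "G3-B").state == "absent"

    def test_female_only_questions_auto_resolve_for_males(self, kb):
        responses = {f"G1.Q{i}": "no" for i in (1, 2, 3, 5, 6)}  # Q4 unanswered
        assert evaluate_group(kb, AnswerSet(sex="male", responses=responses), "G1").state == "absent"
        assert (
            evaluate_group(kb, AnswerSet(sex="female", responses=responses), "G1").state
            == "undetermined"
        )

    def test_unknown_group_raises(self, kb):
        with pytest.raises(KeyError):
            evaluate_group(kb, AnswerSet(), "G9")

    def test_compat_mode_excludes_red_flag_question(self, kb_compat, p2):
        assert evaluate_group(kb_compat, p2, "G1").state == "absent"


class TestEvaluateCondition:
    @staticmethod
    def _findings(**states):
        return {
            g: GroupFinding(group_id=g, state=s)
            for g, s in states.items()
        }

    def test_rule3_case1_on_all_absent(self, kb):
        condition = kb.rule(3).cases[0].condition
        findings = self._findings(**{"G1": "absent", "G2": "absent", "G4-A": "absent"})
        assert evaluate_condition(condition, findings) is Tri.TRUE

    def test_kleene_and_with_unknown(self):
        expr = And(args=[AnyPositive(group="A"), AnyPositive(group="B")])
        findings = self._findings(A="positive-present", B="undetermined")
        assert evaluate_condition(expr, findings) is Tri.UNKNOWN

    def test_kleene_or_true_dominates_unknown(self):
        expr = Or(args=[AnyPositive(group="A"), AnyPositive(group="B")])
        findings = self._findings(A="positive-present", B="undetermined")
        assert evaluate_condition(expr, findings) is Tri.TRUE

    def test_none_positive_negates(self):
        findings = self._findings(A="positive-present")
        assert evaluate_condition(NonePositive(group="A"), findings) is Tri.FALSE

    def test_missing_group_raises(self):
        with pytest.raises(KeyError):
            evaluate_condition(AnyPositive(group="A"), {})


class TestClassify:
    def test_patient1_fires_rule1_case1(self, kb, p1):
        c = classify(kb, p1)
        assert c.status == "determined"
        assert (c.rule_id, c.case_index) == (1, 1)
        assert c.outcome_label == "High possibility of ankle fracture"

    def test_patient1_same_in_compatibility_mode(self, kb_compat, p1):
        c = classify(kb_compat, p1)
        assert (c.rule_id, c.case_index) == (1, 1)
        assert c.compatibility_mode

    def test_complete_all_negative_is_no_injury(self, kb):
        c = classify(kb, _all_negative(kb))
        assert c.status == "determined"
        assert (c.rule_id, c.case_index) == (3, 1)
        assert c.outcome_label == "The patient does not have an injury"

    def test_patient2_strict_fires_rule1_case2(self, kb, p2):
        """Literal rule semantics: G1 positive via Q6, G3-A positive via pain."""
        c = classify(kb, p2)
        assert c.status == "determined"
        assert (c.rule_id, c.case_index) == (1, 2)
        assert not c.compatibility_mode

    def test_patient2_compat_reproduces_published_row(self, kb_compat, p2):
        c = classify(kb_compat, p2)
        assert c.status == "determined"
        assert (c.rule_id, c.case_index) == (2, 1)
        assert c.outcome_label == "High possibility of ankle sprain"
        assert c.compatibility_mode
        assert any("red-flag" in note for note in c.notes)

    def test_partial_answers_report_blocking_leaves(self, kb):
        c = classify(kb, AnswerSet())
        assert c.status == "needs-more-answers"
        assert c.rule_id is None and c.outcome_label is None
        assert c.blocking  # the unknown leaves of the first undecidable case

    def test_trace_is_deterministic(self, kb, p1):
        assert classify(kb, p1) == classify(kb, p1)
        assert classify(kb, p1).trace == classify(kb, p1).trace

    def test_unknown_question_id_rejected(self, kb):
        with pytest.raises(UnknownQuestionError, match="G9.Q1"):
            classify(kb, AnswerSet(responses={"G9.Q1": "yes"}))


class TestTensEligibility:
    def test_all_seven_no_allows_cast(self, kb):
        answers = AnswerSet(
            sex="female", responses={f"G5.Q{i}": "no" for i in range(1, 8)}
        )
        assert tens_eligibility(kb, answers) == "cast-allowed"

    def test_heart_disease_prohibits(self, kb):
        assert tens_eligibility(kb, AnswerSet(responses={"G5.Q1": "yes"})) == "cast-prohibited"

    def test_partial_screen_undetermined(self, kb):
        answers = AnswerSet(
            sex="female", responses={f"G5.Q{i}": "no" for i in (1, 2, 3, 4, 5)}
        )
        assert tens_eligibility(kb, answers) == "undetermined"

    def test_pregnancy_auto_resolves_for_males(self, kb):
        answers = AnswerSet(sex="male", responses={f"G5.Q{i}": "no" for i in (1, 3, 4, 5, 6, 7)})
        assert tens_eligibility(kb, answers) == "cast-allowed"


class TestNextQuestion:
    def test_empty_answers_start_at_g1_q1(self, kb):
        assert next_question(kb, AnswerSet()) == "G1.Q1"

    def test_g1_positive_skips_g2(self, kb):
        """No rule case conjoins a G1-positive literal with any G2 literal."""
        answers = AnswerSet(responses={"G1.Q1": "yes"})
        assert next_question(kb, answers) == "G3-A.Q1"

    def test_none_needed_when_both_determined(self, kb):
        answers = _all_negative(kb)
        answers = answers.model_copy(
            update={"responses": {**answers.responses, **{f"G5.Q{i}": "no" for i in (1, 3, 4, 5, 6, 7)}}}
        )
        assert classify(kb, answers).status == "determined"
        assert tens_eligibility(kb, answers) == "cast-allowed"
        assert next_question(kb, answers) is None

    def test_g5_still_asked_after_diagnosis_determined(self, kb, p1):
        assert next_question(kb, p1) == "G5.Q1"


# --- properties --------------------------------------------------------------

_DIAG = ("G1", "G2", "G3-A", "G3-B", "G4-A", "G4-B")


@settings(max_examples=60, derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from(
            [f"G1.Q{i}" for i in (1, 2, 3, 5, 6)]
            + ["G2.Q1", "G2.Q2", "G2.Q3"]
            + [f"G3-A.Q{i}" for i in (1, 2, 3)]
            + [f"G4-A.Q{i}" for i in (1, 2, 3)]
        ),
        st.sampled_from(["yes", "no"]),
        max_size=12,
    ),
    st.randoms(use_true_random=False),
)
def test_determined_classification_never_retracted(answers_map, rnd):
    """Once determined on partial answers, any completion yields the same verdict."""
    from ankletriage import bundled_kb

    kb = bundled_kb()
    partial = AnswerSet(sex="male", responses=answers_map)
    before = classify(kb, partial)
    if before.status != "determined":
        return
    completed = dict(answers_map)
    for q in kb.questions:
        if q.kind == "body-metric" or q.applicability == "female-only":
            continue
        completed.setdefault(q.id, rnd.choice(["yes", "no"]))
    after = classify(
        kb, AnswerSet(sex="male", responses=completed, weight_kg=70, height_cm=175)
    )
    assert (after.rule_id, after.case_index, after.outcome_label) == (
        before.rule_id,
        before.case_index,
        before.outcome_label,
    )


@settings(max_examples=60, derandomize=True)
@given(
    st.dictionaries(
        st.sampled_from([f"G3-A.Q{i}" for i in (1, 2, 3)]),
        st.sampled_from(["yes", "no"]),
    ),
    st.sampled_from([f"G3-A.Q{i}" for i in (1, 2, 3)]),
    st.sampled_from(["yes", "no"]),
)
def test_group_positivity_is_absorbing(answers_map, qid, value):
    """Adding an answer never moves a group out of positive-present."""
    from hypothesis import assume

    from ankletriage import bundled_kb

    kb = bundled_kb()
    assume(qid not in answers_map)
    base = AnswerSet(responses=answers_map)
    before = evaluate_group(kb, base, "G3-A")
    after = evaluate_group(kb, base.with_response(qid, value), "G3-A")
    if before.state == "positive-present":
        assert after.state == "positive-present"
    if value == "yes":  # an added positive finding always promotes
        assert after.state == "positive-present"
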