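# Methods

## Scope and model

`ankletriage` re-implements, as a reusable and tested engine, a
published knowledge-based triage system for ankle injuries: a
questionnaire derived from the Ottawa Ankle Rules, five IF-THEN
production rules over group-level symptom aggregates, cast/TENS
contraindication screening, two care paths (visit clinician / home
care), and stored recovery plans. The engine is deliberately
data-driven: the rule base, question polarities, BMI threshold, rule
priority, outcome→path mapping, and compatibility flags are all fields
of the knowledge-base document, not code.

Out of scope by design: any mobile/UI layer, persistence, messaging,
imaging, device control, and any probabilistic or learned scoring —
outcomes are the rule base's categorical labels only. Pain "prediction"
is implemented as descriptive trend summaries (latest, mean, OLS slope
in score/day) because no predictive formula is specified anywhere in
the source material; inventing one would be unanchored.

## Three-valued evaluation and determinacy

Partial questionnaires are first-class. Each group aggregates to
positive-present (≥ 1 applicable question shows its finding; this
short-circuits over unanswered questions), absent (all applicable
questions answered, none positive), or undetermined. Rule conditions
are evaluated over these aggregates in Kleene strong three-valued
logic, which is sound with respect to every completion: once a leaf is
true or false on the answers given, it stays so as answers accumulate
(positivity is absorbing; absence requires completeness).

The classifier scans diagnostic rules in priority order and cases in
declared order. It stops at the first case evaluating **true** — this
verdict is final under any completion, because every higher-priority
case has already evaluated false and false is stable — or at the first
case evaluating **unknown**, reported as needs-more-answers with the
unknown leaves listed as blocking. This gives the determined-means-final
contract: a determined classification is never retracted when the
remaining questions are answered, which the suite checks by randomized
completion. The first worked example depends on it: that patient is
classified with the sprain groups entirely unanswered.

No case in the bundled rule base mentions the same group twice, so
Kleene "unknown" coincides with genuine contingency (there exist
completions both ways); the needs-more-answers report is therefore
never spuriously conservative for the bundled KB.

## Conflict resolution and the rule audit

The printed diagnostic cases overlap: enumerating all 2⁶ = 64
assignments of {positive, absent} to the six diagnostic groups shows 19
assignments satisfied by more than one case (and zero satisfied by
none). The source text states no tie-break, so the engine applies
severity-ordered first match — fracture (Rule 1) over sprain (Rule 2)
over no-injury (Rule 3) — stored as `settings.rule_priority`. The
rationale is purely clinical conservatism: never under-triage a
possible fracture. The audit module derives these numbers with its own
literal two-valued evaluator, independent of the engine's Kleene code
path, and the 0-gap / 19-overlap values are pinned as regressions.

The audit works at group-aggregate level rather than raw answer level
(2³² vectors) because every rule condition factors through the six
aggregates; `canonical_answers` maps any aggregate assignment to a
deterministic complete answer set (first applicable boolean question of
a positive group carries the finding; polarity respected, so an absent
Ottawa group answers "yes" to the balance question), which is how the
engine is checked against the oracle end to end.

## The two published worked examples, and compatibility mode

Patient 1 reproduces exactly (Rule 1 Case 1, fracture) under any mode.
Patient 2 is internally inconsistent in the source: they answer the
general red-flag question G1.Q6 affirmatively, which makes G1 positive,
and with pain present a literal reading fires Rule 1 Case 2 (fracture)
— yet the published applied rule is "Rule 2: Case 1" (sprain), whose
condition requires no G1 finding. The only reading found that
reproduces the published row is to exclude G1.Q6 from the G1 aggregate
and record it as a separate red-flag annotation. That reading is
shipped as the `exclude_G1_Q6_from_aggregate` compatibility flag
(CLI `--mode compatibility`); strict literal semantics are the default,
and every report and classification object is stamped with the mode
that produced it. Both behaviors are pinned as regression tests.

## Tunable parameters

- `bmi_elevated_threshold` (kg/m², default 25.0): the source says only
  "elevated BMI"; 25 is the WHO overweight cut-off. The comparison is
  inclusive (≥) — the boundary direction is unstated and must be fixed
  for determinism.
- `rule_priority` (default [1, 2, 3]): see conflict resolution above.
- `outcome_paths`: fracture→visit-clinician, sprain→home-care,
  no-injury→no-action. The source describes the two paths but never
  states the routing; the clinician branch lists x-ray/cast (fracture
  procedures) and the home branch rest + exercises (sprain
  management), hence this mapping — kept as KB data so it is editable.
- Female-only questions (pregnancy) auto-resolve to "no finding" for
  non-female patients and are asked or sampled only for female records.
- Question order: the KB's declared group order (G1 → G2 → G3-A → G3-B
  → G4-A → G4-B → G5), questions in declared order — the only ordering
  the source evidences. `next_question` additionally skips groups whose
  aggregate is already fixed and groups that cannot change the
  still-undetermined part of the (classification, eligibility) pair,
  determined by enumerating completions of the undetermined groups.

## Recovery plans

The avulsion-type fracture plan (weber-a) carries the stated timeline:
6 weeks healing, residual pain/swelling up to 6 months. The spiral-type
plan (weber-b) is specified in the source only as "like Weber A" and is
therefore stored with the same timeline and `provisional = true`. The
sprain plan's detailed content lives in supplementary material not
reproduced here; the shipped plan is minimal home-care guidance (RICE),
marked provisional, with a 2-week healing / 3-month residual horizon
chosen as a standard mild-sprain course — the schema requires a
positive duration, and the flag makes its status explicit. Phase texts
for weeks 7–12 are the package's own summaries of standard
cast-removal rehabilitation, not transcriptions.

## Synthetic cohorts

The generator emulates a walk-in population for an ankle-injury triage
app: per-question Bernoulli finding probabilities (defaults per group:
contraindications and TENS contraindications 0.05, Ottawa findings
0.30, fracture signs 0.25 ankle / 0.10 systemic, sprain signs
0.35/0.30), P(female) = 0.5, and an elevated-BMI probability of 0.35.
The elevated-BMI indicator is sampled directly and the weight/height
pair is then constructed on the intended side of the threshold with a
0.5 kg/m² guard band, so finding probabilities — not an incidental
weight distribution — control the body-metric findings; setting every
probability to zero provably yields an all-negative, no-injury cohort.
One seeded NumPy generator per cohort; identical (seed, config) gives
identical cohorts, byte-identical when exported.

What passing tests on synthetic cohorts do **not** show: anything about
real symptom prevalence, co-occurrence structure (findings are sampled
independently), or diagnostic accuracy against ground truth. The
cohorts exercise the engine's contracts, nothing more.

## Numerical and degenerate-input choices

BMI = weight / (height/100)²; non-positive inputs are domain errors.
Pain scores are integers 0–10; reports must arrive in timestamp order;
the trend slope is ordinary least squares over (days since first
report, score) and is reported absent with fewer than two distinct
time points. Answer files accept JSON (single patient) and CSV (cohort,
one column per question id); empty cells are unanswered.

## Problem sizes

The audit space is exact and tiny (64 assignments × 8 case conditions);
the eligibility partition is enumerated over all 2⁷ screening vectors;
monotone determinacy is checked on 200 random partial answer sets; the
acceptance script classifies a 500-patient cohort. The full test suite
and the acceptance script each run in seconds on one CPU.

## Known limitations

- The rule base is reproduced as printed, including clinically odd
  consequences (a single lifestyle finding such as smoking satisfies
  the fracture-sign disjunct; a no-injury case ignores G3-B and G4-B
  findings entirely). The audit makes such properties visible; it does
  not editorialise.
- The strict/compatibility divergence on worked example 2 is inherent
  to the source material; the package keeps both readings and labels
  them rather than silently choosing one.
- TENS intensity is an opaque ordinal with no adjustment policy, and
  no notification transport exists — emergency stops are returned as
  event records for the caller to route.
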