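# ankletriage

A knowledge-based expert-system engine for first-line ankle-injury
triage. It is written for people building or studying clinical
decision-support tools: the clinical knowledge lives in a declarative,
versioned document (JSON or YAML), and the engine — a tri-state
forward-chaining classifier — is generic over that document, so the
rule base can be audited, edited, and re-validated without touching
code.

## The model

A patient answers a structured questionnaire organised into seven
groups built around the **Ottawa Ankle Rules**: G1 (contraindications
to applying the Ottawa rules), G2 (the Ottawa findings themselves:
malleolar and midfoot tenderness, inability to bear weight), G3-A/G3-B
(ankle-fracture signs), G4-A/G4-B (ankle-sprain signs), and G5 (TENS /
cast contraindications such as heart disease, pregnancy, epilepsy).
Each question has an explicit *finding polarity*: most flag a finding
on "yes", the weight-bearing/balance question flags one on "no", and
the two BMI items flag one when weight/(height)² ≥ a configurable
threshold (default 25 kg/m²).

Diagnosis is by IF-THEN production rules over group aggregates
`any-positive(G)` / `none-positive(G)`, e.g.

```
Rule 1 (ankle fracture), Case 1:
    none-positive(G1) AND any-positive(G2)
                      AND (any-positive(G3-A) OR any-positive(G3-B))
```

Five rules (ten cases) cover fracture, sprain, no-injury, and cast
use/prohibition. Because a questionnaire may be partial, conditions are
evaluated in **Kleene strong three-valued logic**; a classification is
reported as *determined* only when no completion of the unanswered
questions could change it, so a determined verdict is never retracted.
The printed diagnostic rules overlap (the bundled audit finds 19 of the
64 possible group-finding assignments matched by more than one case),
so rules are scanned in a severity priority order — fracture before
sprain before no-injury — that never under-triages a possible fracture.

A brute-force audit module enumerates all 2⁶ assignments of findings to
the six diagnostic groups with an independent two-valued evaluator and
reports gaps (no rule fires — the bundled rule base has none), overlaps,
and the priority-resolved verdict table; it doubles as the oracle the
engine is tested against. A seeded synthetic-cohort generator produces
complete, KB-consistent patients for simulation and testing.

## Worked example

Classify the first bundled example patient (positive Ottawa findings,
multiple fracture signs):

```python
from ankletriage import patient_one, write_answers_json
write_answers_json(patient_one(), "patient1.json")
```

```
$ ankletriage classify --answers patient1.json
KB version:  1.0   mode: strict
Applied rule: Rule 1: Case 1
Outcome:      High possibility of ankle fracture
Cast/TENS eligibility: undetermined
Care path:    visit-clinician
Narrative:    High possibility of ankle fracture. Visit a clinician for further
assessment; expected procedures include x-rays, applying a cast, and
clinician-administered TENS therapy. TENS/cast eligibility is not yet determined.
```

Rule 1 Case 1 fired: no Ottawa contraindication, at least one Ottawa
finding, at least one fracture sign — so the patient is routed to a
clinician. Eligibility is undetermined because the patient never
answered the G5 screening group. The second bundled patient
(`patient_two`) answers the general red-flag question G1.Q6 "yes";
strict rule semantics classify them Rule 1 Case 2 (fracture), while
`--mode compatibility` excludes G1.Q6 from the G1 aggregate (recording
it as a red-flag note) and yields Rule 2 Case 1 (sprain). Every report
is stamped with the mode that produced it; see `docs/methods.md` for
why both readings are kept.

Audit the rule base and print a recovery plan:

```
$ ankletriage audit
gaps: 0
overlaps: 19
  positive {G4-B} -> Rule 2: Case 1, Rule 3: Case 1
  ...

$ ankletriage plan weber-a
Recovery plan: weber-a
  healing duration: 6 weeks
  residual symptoms may persist: 6 months
  ...
```

Other commands: `validate` (schema + invariant check of a KB document),
`diagnose` (interactive session that asks only questions that can still
change the verdict), `simulate` (seeded synthetic cohort + outcome
tally), `export-kb` (JSON/YAML round-trip).

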