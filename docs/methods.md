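# Methods

## Scope and data model

The package models a nursing decision-support chain for delirium in
long-term care: (1) screen a resident's risk from categorical/binary risk
factors via a rule base, (2) confirm with the S-CAM screening logic,
(3) issue and track a preventive-intervention checklist, (4) evaluate the
learner with a repeated-CV protocol, (5) score usability surveys. All
domain objects (schema, records, rules, plans, results) are plain
dataclasses with invariant checks at construction; cohorts and rule bases
round-trip through CSV/JSON.

The shipped risk-factor schema has exactly 24 factors: 14 named clinical
factors (age ≥ 65, disease severity, abnormal BUN, dehydration,
water–electrolyte imbalance, nutritional imbalance, hypoxia, infection,
sleep disorder, surgery with general anaesthesia, oedema, multiple
comorbidities, pain, pain-medicine use) and 10 placeholder factors
(`factor_15` … `factor_24`). The engine never hard-codes the factor list; a
replacement schema can be supplied as JSON. Missing values are first-class:
the bedside form collects only a subset (~10) of the algorithm's factors, so
every operation tolerates MISSING, which by convention never satisfies a
rule condition — a conservative choice that also makes support/confidence
counting and matching-degree computation consistent with each other.

## Rule semantics

Support and confidence use the standard class-association-rule definitions
over the training cohort (support = joint antecedent+consequent frequency
in percent of all records; confidence = conditional frequency). This choice
makes the shipped tertile cut-offs arithmetically coherent with a
173-record cohort: 3/173 ≈ 1.73%, 6/173 ≈ 3.47%. The scope (training
cohort) is recorded in every rule base's provenance block.

## LEM2 induction

`lem2_induce` implements the classic local-covering procedure per decision
class. Inconsistent tables are handled through the rough-set lower
approximation by default (certain rules); the upper approximation is
available by configuration. The greedy inner loop selects the candidate
attribute–value pair maximising overlap with the uncovered goal; ties are
broken by (1) smallest total block, (2) schema factor order and declared
value order. The rationale: LEM2 leaves the tie-break open, and a fixed
ordering makes induction a pure function of
(cohort, config), which the determinism tests rely on. After a consistent
complex is found, conditions are dropped in insertion order when redundant,
and finally redundant rules are dropped when the remaining rules still
cover the approximation. Goal records that cannot be covered (e.g. all
conditions MISSING) are dropped with a logged warning rather than looping.
Rules below `min_support_pct` (default 0) are discarded after annotation.

`Lem2Classifier` wraps induction in a scikit-learn estimator
(fit/predict/get_params), inferring a schema from the training frame when
none is given, so it composes with `sklearn.base.clone` and the CV harness;
comparator learners from sklearn plug into the same harness unchanged.

## Inference

Matching degree is the satisfied-condition percentage. Best-rule selection
maximises matching degree, then support × confidence, then lowest rule id —
the residual id tie-break is a package choice for reproducibility. The
reported risk percentage is the winning rule's support, because the tertile
stratification is defined on support. Boundary semantics: the medium band is
the closed interval [1.73, 3.47]; strictly below is low, strictly above is
high. Stratification applies only when the winning rule decides delirium;
otherwise the level is `none` and no alarm is raised. The alarm is an event
record (timestamp, pseudonym, channels — screen and vibration by default)
appended to a JSON-lines audit log, not a hardware action.
`min_matching_degree` defaults to 0 so a partial match always yields an
answer, mirroring the always-on risk display; stricter deployments can
raise it, in which case the engine returns a no-match signal.

## S-CAM

Positivity = inattention YES AND ≥1 YES in Box 1 (steps 1–2) AND ≥1 YES in
Box 2 (steps 3–4); any consciousness level other than *normal* (vigilant,
lethargic, stuporous, comatose) counts as a step-4 YES, following CAM
convention since the instrument's own level→YES mapping is not published.
Note the literal rule makes Box 1 redundant given a step-2 YES; the
conventional CAM logic (feature 1 AND feature 2 AND (feature 3 OR
feature 4)) is available via `standard_cam=True` but is deliberately not
the default. Delirium subtype (hyperactive/hypoactive/mixed) is recorded,
never computed — no decision criteria exist for it. The licensed instrument
text is not reproduced; only the decision logic is implemented.

## Interventions

The shipped catalogue transcribes the three preventive components
(orientation: 7 items; environmental: 6; risk avoidance: 10). Eligibility:
the strict policy issues the plan only for high-risk patients screening
positive; the default *preventive* policy also issues it for high risk
alone or any positive screen, on the reading that the components are
prophylactic. All three categories are always issued together. The
performance rate is 100 · completed/total, half-up rounded to one decimal
for display parity.

## Evaluation harness

`stratified_repeated_cv` re-stratifies each repeat with a per-repeat seed
drawn from a master generator, so fold draws are independent across repeats
yet fully reproducible; within a repeat every record is tested exactly
once. Per-class F1 is computed from confusion counts with the
degenerate-class convention F1 = 0 when a class has no predictions and no
truths (a `drop_empty` flag excludes such classes instead); macro-F1 is the
unweighted class mean, weighted-F1 weights by true-class counts — both
cross-checked against scikit-learn in the tests. AUC uses the rank statistic
with tie correction (via scikit-learn); learners without scores contribute
0/1 predicted labels. The five-fold single-repeat protocol used for
prior-cohort metrics is the same operation with k = 5, repeats = 1.

The paired Wilcoxon signed-rank test drops zero differences, uses the exact
null distribution for up to 25 non-zero pairs and the tie-corrected normal
approximation beyond. The exact branch enumerates the distribution of W+ by
dynamic programming over doubled ranks, which stays exact in the presence of
tied absolute differences (where standard exact routines fall back to an
approximation). The effect size is the matched-pairs rank-biserial
correlation r = (W⁺ − W⁻)/(W⁺ + W⁻), chosen because it is bounded in
[−1, 1] and standard for this test.

## Synthetic cohorts

The generator emulates a low-prevalence LCF cohort: default n = 173, 24
binary factors with independent per-factor positive probability 0.20 (a
typical geriatric risk-factor prevalence), base delirium prevalence 0.081.
Labels are rule-driven: any record fully satisfying a planted delirium rule
is a case; a residual Bernoulli component among uncovered records tops
incidence up toward the base prevalence when the planted rules fire rarely
(probability max(0, (0.081·n − covered)/(n − covered))); optional label
noise then flips labels independently. The default planted mechanism is
three two-factor delirium rules over disjoint factor pairs
(age ≥ 65 ∧ dehydration; infection ∧ sleep disorder;
hypoxia ∧ general-anaesthesia surgery), which at the default marginals
cover ≈ 11% of records, so the residual component is usually inactive and
noiseless cohorts are consistent tables.

What this emulates — and does not. The generator reproduces the *discrete,
rule-governed* structure the engine assumes, which makes planted-rule
recovery a well-defined correctness probe. It does not model correlated
comorbidities, longitudinal assessments, informative missingness, or the
messiness of real nursing documentation; passing recovery tests therefore
demonstrates algorithmic correctness, not clinical performance. No real
patient-level data ship with or are reachable from this package, so no
clinical performance claim is computed here.

## SUS scoring

Default scoring is the standard Brooke rule: odd items contribute
(value − 1), even items (5 − value), total × 2.5, spanning exactly [0, 100]
with the above-average benchmark at ≥ 68. A literal raw-sum × 2.5 mode is
provided for transparency; it spans [25, 125] and is therefore incompatible
with a 0–100 scale, which is why it is not the default.

## Problem sizes and numerical choices

Test and acceptance workloads use cohorts of 80–500 records; rule recovery
runs ten seeds at n = 500, CV protocols run 10×2 on ~120–173 records —
sizes matched to the reference study design. Floating-point comparisons in
the tests use absolute tolerances ≤ 0.01 on percentage quantities;
support = confidence × coverage is asserted to 1e−9. All randomness flows
through explicit integer seeds (numpy `default_rng`); repeat seeds are
drawn below 2³¹ from the master seed.

## Known limitations

- LEM2 handles categorical data only; continuous factors must be
  discretised upstream (the shipped schema is binary).
- Rule-base updating is full re-induction, not incremental learning.
- The S-CAM implementation is the decision logic only and must not be used
  as a clinical instrument.
- `classify`'s strict mode falls back to partial matching, so it always
  answers; abstention requires raising `min_matching_degree`.
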