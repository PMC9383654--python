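"""LEM2 induction checked against exhaustive subset-enumeration oracles."""

import itertools

import numpy as np
import pytest

from delirisk import (
    Cohort,
    InductionConfig,
    Lem2Classifier,
    classify,
    lem2_induce,
)
from delirisk.rules import Condition, Rule, RuleBase

from conftest import make_record, make_schema


# ---------------------------------------------------------------------------
# independent oracle: enumerate every attribute-value complex on a toy table
# ---------------------------------------------------------------------------

def block_of(conditions, cohort):
    return frozenset(
        i for i, rec in enumerate(cohort) if all(c.satisfied_by(rec) for c in conditions)
    )


def lower_approximation(cohort, cls):
    groups = {}
    for i, rec in enumerate(cohort):
        key = tuple(rec.value(n) for n in cohort.schema.factor_names)
        groups.setdefault(key, []).append(i)
    out = set()
    for members in groups.values():
        if all(cohort.records[i].label == cls for i in members):
            out.update(members)
    return frozenset(out)


def all_minimal_consistent_complexes(cohort, B):
    """Every condition set whose block is a non-empty subset of B and which
    loses that property when any single condition is dropped."""
    pairs = [
        Condition(f.name, v)
        for f in cohort.schema.factors
        for v in f.allowed_values
    ]
    found = []
    for size in range(1, len(cohort.schema.factors) + 1):
        for combo in itertools.combinations(pairs, size):
            if len({c.factor for c in combo}) != size:
                continue
            blk = block_of(combo, cohort)
            if not blk or not blk <= B:
                continue
            minimal = all(
                not (block_of(tuple(c for c in combo if c is not drop), cohort) <= B)
                for drop in combo
            ) if size > 1 else True
            if size > 1 and not minimal:
                continue
            found.append(frozenset(combo))
    return found


def assert_valid_local_covering(rulebase, cohort, cls):
    B = lower_approximation(cohort, cls)
    rules = rulebase.for_decision(cls)
    minimal_complexes = all_minimal_consistent_complexes(cohort, B)
    covered = set()
    for rule in rules:
        blk = block_of(rule.conditions, cohort)
        assert blk <= B, f"rule {rule.rule_id} is inconsistent"
        assert frozenset(rule.conditions) in minimal_complexes, (
            f"rule {rule.rule_id} is not a minimal consistent complex"
        )
        covered |= blk
    assert covered == B, "rule set does not exactly cover the class approximation"


class TestLem2OnToyTables:
    def test_toy_table_covering_is_consistent_minimal_complete(self, toy_cohort):
        rb = lem2_induce(toy_cohort)
        for cls in ("delirium", "non-delirium"):
            assert_valid_local_covering(rb, toy_cohort, cls)
        for rule in rb.for_decision("delirium"):
            assert rule.confidence == 100.0

    def test_perfect_separator_gives_single_condition_rules(self):
        schema = make_schema(3)
        records = []
        for i in range(4):
            records.append(make_record(schema, ("yes", "yes" if i % 2 else "no", "no"),
                                       "delirium", pid=f"d{i}"))
        for i in range(4):
            records.append(make_record(schema, ("no", "no" if i % 2 else "yes", "yes"),
                                       "non-delirium", pid=f"n{i}"))
        cohort = Cohort(schema=schema, records=tuple(records))
        rb = lem2_induce(cohort)
        assert len(rb.for_decision("delirium")) == 1
        assert len(rb.for_decision("non-delirium")) == 1
        for rule in rb:
            assert len(rule.conditions) == 1
            assert rule.conditions[0].factor == "f1"

    def test_duplicate_records_leave_rules_unchanged(self, toy_cohort):
        rb = lem2_induce(toy_cohort)
        doubled = toy_cohort.with_records(toy_cohort.records + toy_cohort.records)
        rb2 = lem2_induce(doubled)
        assert [(r.conditions, r.decision) for r in rb] == [
            (r.conditions, r.decision) for r in rb2
        ]
        # supports rescale but stay equal: same fraction of a doubled cohort
        assert [r.support for r in rb] == [r.support for r in rb2]

    def test_determinism(self, toy_cohort):
        config = InductionConfig(seed=42)
        assert lem2_induce(toy_cohort, config) == lem2_induce(toy_cohort, config)

    def test_single_class_cohort_warns_and_covers_it(self, schema3):
        records = tuple(
            make_record(schema3, ("yes", "no", "yes"), "delirium", pid=f"p{i}")
            for i in range(3)
        )
        cohort = Cohort(schema=schema3, records=records)
        with pytest.warns(UserWarning, match="non-delirium"):
            rb = lem2_induce(cohort)
        assert rb.for_decision("delirium")
        assert not rb.for_decision("non-delirium")

    def test_inconsistent_table_lower_approximation(self, schema3):
        """Contradictory duplicate vectors fall out of the lower approximation."""
        records = (
            make_record(schema3, ("yes", "yes", "yes"), "delirium", pid="a"),
            make_record(schema3, ("yes", "yes", "yes"), "non-delirium", pid="b"),
            make_record(schema3, ("no", "no", "no"), "non-delirium", pid="c"),
            make_record(schema3, ("no", "yes", "no"), "delirium", pid="d"),
        )
        cohort = Cohort(schema=schema3, records=records)
        rb = lem2_induce(cohort)
        for cls in ("delirium", "non-delirium"):
            assert_valid_local_covering(rb, cohort, cls)

    def test_unlabelled_cohort_rejected(self, schema3):
        cohort = Cohort(schema=schema3, records=(make_record(schema3, ("yes",) * 3),))
        with pytest.raises(ValueError, match="labelled"):
            lem2_induce(cohort)


class TestClassify:
    def test_single_full_match_decides(self, small_rulebase, schema3):
        rec = make_record(schema3, ("no", "no", "no"))
        assert classify(small_rulebase, rec) == "non-delirium"

    def test_no_full_match_falls_back_to_matching_degree(self, small_rulebase, schema3):
        # matches rule 1 at 50%, rule 2 at 0%, rule 3 at 50%;
        # tie on degree -> product: rule 3 (50*90) beats rule 1 (2*100)
        rec = make_record(schema3, ("yes", "no", "no"))
        assert classify(small_rulebase, rec) == "non-delirium"

    def test_two_full_matches_resolved_by_product(self, schema3):
        rules = (
            Rule(1, (Condition("f1", "yes"),), "delirium", 2.0, 100.0),
            Rule(2, (Condition("f2", "yes"),), "non-delirium", 4.0, 40.0),
        )
        rb = RuleBase(schema=schema3, rules=rules)
        rec = make_record(schema3, ("yes", "yes", "no"))
        # products 200 vs 160 -> delirium wins
        assert classify(rb, rec) == "delirium"

    def test_empty_rulebase_rejected(self, schema3):
        rb = RuleBase(schema=schema3, rules=())
        with pytest.raises(ValueError, match="empty"):
            classify(rb, make_record(schema3, ("yes", "no", "no")))

    def test_training_accuracy_100_on_consistent_table(self, toy_cohort):
        rb = lem2_induce(toy_cohort)
        for rec in toy_cohort:
            assert classify(rb, rec) == rec.label


class TestLem2Classifier:
    def test_sklearn_contract(self, toy_cohort):
        from sklearn.base import clone

        df = toy_cohort.to_frame()[list(toy_cohort.schema.factor_names)]
        y = np.asarray(toy_cohort.labels)
        clf = Lem2Classifier(schema=toy_cohort.schema)
        cloned = clone(clf)
        cloned.fit(df, y)
        assert set(cloned.classes_) == {"delirium", "non-delirium"}
        assert (cloned.predict(df) == y).all()
        assert len(cloned.rulebase_) > 0

    def test_schema_inference_from_plain_arrays(self):
        X = [["yes", "no"], ["no", "yes"], ["yes", "yes"], ["no", "no"]]
        y = ["delirium", "non-delirium", "delirium", "non-delirium"]
        clf = Lem2Classifier().fit(X, y)
        assert (clf.predict(X) == np.asarray(y)).all()

    def test_fit_cohort_shortcut(self, toy_cohort):
        clf = Lem2Classifier().fit_cohort(toy_cohort)
        assert clf.rulebase_.schema == toy_cohort.schema
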