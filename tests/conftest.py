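import pytest

from delirisk import (
    Cohort,
    Condition,
    PatientRecord,
    RiskFactor,
    RiskFactorSchema,
    Rule,
    RuleBase,
)


def make_schema(n_factors: int = 3) -> RiskFactorSchema:
    return RiskFactorSchema(
        factors=tuple(RiskFactor(f"f{i}") for i in range(1, n_factors + 1))
    )


def make_record(schema, values, label=None, pid="p"):
    """values: iterable of 'yes'/'no' in schema factor order."""
    return PatientRecord(
        patient_id=pid,
        values=dict(zip(schema.factor_names, values)),
        label=label,
    )


@pytest.fixture
def schema3():
    return make_schema(3)


@pytest.fixture
def toy_cohort(schema3):
    """Consistent 8-record, 3-binary-factor table with a planted structure:

    delirium iff (f1=yes AND f2=yes) OR (f3=yes AND f1=no).
    """
    rows = [
        (("yes", "yes", "no"), "delirium"),
        (("yes", "yes", "yes"), "delirium"),
        (("no", "no", "yes"), "delirium"),
        (("no", "yes", "yes"), "delirium"),
        (("yes", "no", "no"), "non-delirium"),
        (("yes", "no", "yes"), "non-delirium"),
        (("no", "yes", "no"), "non-delirium"),
        (("no", "no", "no"), "non-delirium"),
    ]
    records = tuple(
        make_record(schema3, vals, label, pid=f"p{i}") for i, (vals, label) in enumerate(rows)
    )
    return Cohort(schema=schema3, records=records)


@pytest.fixture
def small_rulebase(schema3):
    rules = (
        Rule(1, (Condition("f1", "yes"), Condition("f2", "yes")), "delirium", 2.0, 100.0),
        Rule(2, (Condition("f3", "yes"),), "delirium", 4.0, 40.0),
        Rule(3, (Condition("f1", "no"), Condition("f2", "no")), "non-delirium", 50.0, 90.0),
    )
    return RuleBase(schema=schema3, rules=rules)
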