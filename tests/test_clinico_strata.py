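"""Personal/family history categories and carrier stratification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from melpanel import (
    CarrierProfile,
    ClinicalRecord,
    FamilyCancerHistory,
    PersonalCategory,
    RiskClass,
    TwoByTwo,
    assign_personal_category,
    category_carrier_table,
    multiplicity_or,
    odds_ratio,
)
from melpanel.clinico_strata import MelanomaSite, Sex


def rec(sid="p1", n_mel=1, other=False, age=40.0, fch=FamilyCancerHistory.NEGATIVE):
    return ClinicalRecord(
        subject_id=sid,
        sex=Sex.F,
        age_first_melanoma=age,
        n_primary_melanomas=n_mel,
        has_other_primary_cancer=other,
        melanoma_site=MelanomaSite.TRUNK,
        fch=fch,
    )


@pytest.mark.parametrize(
    "n_mel,other,age,expected",
    [
        (2, False, 40, PersonalCategory.MULTI_MEL),
        (2, True, 40, PersonalCategory.MULTI_MEL_PLUS_OTHER),
        (1, True, 60, PersonalCategory.MEL_PLUS_OTHER),
        (1, False, 24, PersonalCategory.MEL_ONLY_LT25),
        (1, False, 25, PersonalCategory.MEL_ONLY_GE25),  # boundary: 25 is GE25
        (1, False, 70, PersonalCategory.MEL_ONLY_GE25),
    ],
)
def test_assign_personal_category(n_mel, other, age, expected):
    assert assign_personal_category(rec(n_mel=n_mel, other=other, age=age)) is expected


@given(
    st.integers(1, 5),
    st.booleans(),
    st.floats(0, 100, allow_nan=False),
)
def test_category_assignment_is_a_partition(n_mel, other, age):
    """Every valid record maps to exactly one of the five categories."""
    cat = assign_personal_category(rec(n_mel=n_mel, other=other, age=age))
    assert isinstance(cat, PersonalCategory)
    others = [c for c in PersonalCategory if c is not cat]
    assert len(others) == 4


def _cohort_with_marginals():
    """264 records with the reference personal-history row counts
    6 / 17 / 71 / 36 / 134."""
    spec = [
        (6, dict(n_mel=2, other=True, age=45)),
        (17, dict(n_mel=2, other=False, age=37)),
        (71, dict(n_mel=1, other=True, age=47)),
        (36, dict(n_mel=1, other=False, age=20)),
        (134, dict(n_mel=1, other=False, age=37)),
    ]
    records = []
    i = 0
    for n, kw in spec:
        for _ in range(n):
            i += 1
            records.append(rec(sid=f"p{i:03d}", **kw))
    return records


def test_reference_marginals_partition_to_264():
    records = _cohort_with_marginals()
    counts = {}
    for r in records:
        counts[assign_personal_category(r)] = counts.get(assign_personal_category(r), 0) + 1
    assert sum(counts.values()) == 264
    assert counts[PersonalCategory.MULTI_MEL_PLUS_OTHER] == 6
    assert counts[PersonalCategory.MULTI_MEL] == 17
    assert counts[PersonalCategory.MEL_PLUS_OTHER] == 71
    assert counts[PersonalCategory.MEL_ONLY_LT25] == 36
    assert counts[PersonalCategory.MEL_ONLY_GE25] == 134


def _profile(sid, cls, multi=False):
    variants = tuple(("NBN", f"k{i}") for i in range(2 if multi else 1))
    return CarrierProfile(
        subject_id=sid,
        plp_variants=variants,
        classes_hit=frozenset({cls}),
        assigned_class=cls,
        is_multi=multi,
    )


def _multiplicity_cohort():
    """89 multi-tumor / 164 single-melanoma records (after excluding 11
    multi-variant carriers) with 14 and 10 clinically relevant carriers."""
    records, profiles = [], []
    i = 0

    def add(n, multi_tumor, carrier, multi_variant=False):
        nonlocal i
        for _ in range(n):
            i += 1
            sid = f"s{i:03d}"
            records.append(rec(sid=sid, n_mel=2 if multi_tumor else 1, age=40))
            if carrier:
                profiles.append(_profile(sid, RiskClass.CANCER_SYNDROME, multi=multi_variant))

    add(14, True, True)
    add(75, True, False)
    add(10, False, True)
    add(154, False, False)
    # multi-variant carriers are excluded from both strata
    add(6, True, True, multi_variant=True)
    add(5, False, True, multi_variant=True)
    return records, profiles


def test_multiplicity_or_reproduces_headline_table():
    records, profiles = _multiplicity_cohort()
    r = multiplicity_or(records, profiles)
    assert (r.table.a, r.table.b, r.table.c, r.table.d) == (14, 75, 10, 154)
    assert r.or_point == pytest.approx(2.87, abs=0.01)
    assert r.ci_low == pytest.approx(1.2, abs=0.05)
    assert r.ci_high == pytest.approx(6.8, abs=0.05)
    # no independent math: identical to the burden cross-product
    assert r.or_point == pytest.approx(odds_ratio(TwoByTwo(14, 75, 10, 154)))


def test_multiplicity_or_equal_fractions_is_one():
    records, profiles = [], []
    for i in range(20):
        sid = f"e{i}"
        records.append(rec(sid=sid, n_mel=2 if i < 10 else 1))
        if i % 5 == 0:  # 2 carriers in each stratum of 10
            profiles.append(_profile(sid, RiskClass.HIGH_MODERATE_MELANOMA))
    r = multiplicity_or(records, profiles)
    assert r.or_point == pytest.approx(1.0)


def test_category_table_multiple_melanoma_enrichment():
    """7/16 multiple-melanoma carriers vs 29/164 single-melanoma reference."""
    records, profiles = [], []
    i = 0

    def add(n, n_mel, other, age, carriers):
        nonlocal i
        for j in range(n):
            i += 1
            sid = f"q{i:03d}"
            records.append(rec(sid=sid, n_mel=n_mel, other=other, age=age))
            if j < carriers:
                profiles.append(_profile(sid, RiskClass.CANCER_SYNDROME))

    add(16, 2, False, 40, 7)    # multiple melanoma
    add(164, 1, False, 40, 29)  # melanoma only (reference pool)
    df = category_carrier_table(records, profiles, axis="personal")
    row = df[df["category"] == PersonalCategory.MULTI_MEL.name].iloc[0]
    assert row["carriers"] == 7 and row["n"] == 16
    assert row["proportion"] == pytest.approx(7 / 16)
    ref = df[df["category"].str.startswith("reference")].iloc[0]
    assert ref["carriers"] == 29 and ref["n"] == 164
    assert row["p_fisher_vs_reference"] < 0.05


def test_family_axis_drops_unknown_and_uses_negative_reference():
    records = [
        rec(sid="f1", fch=FamilyCancerHistory.POSITIVE_WITH_MELANOMA),
        rec(sid="f2", fch=FamilyCancerHistory.NEGATIVE),
        rec(sid="f3", fch=FamilyCancerHistory.UNKNOWN),
    ]
    df = category_carrier_table(records, [], axis="family")
    assert FamilyCancerHistory.UNKNOWN.name not in set(df["category"])
    assert df["n"].iloc[:-1].sum() == 2


def test_all_noncarriers_gives_zero_proportions_and_p_one():
    records = [rec(sid=f"z{i}", n_mel=2 if i < 3 else 1) for i in range(10)]
    df = category_carrier_table(records, [], axis="personal")
    assert (df["proportion"].fillna(0) == 0).all()
    ps = df["p_fisher_vs_reference"].dropna()
    assert np.allclose(ps, 1.0)


def test_invalid_axis_errors():
    with pytest.raises(ValueError, match="axis"):
        category_carrier_table([], [], axis="bogus")
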