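"""Burden statistics: OR/CI/test oracles, carrier profiles, table modes."""

import math
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from melpanel import (
    BurdenMode,
    CarrierProfile,
    RiskClass,
    TwoByTwo,
    build_carrier_profiles,
    chi2_p,
    class_table,
    fisher_p,
    gene_burden,
    odds_ratio,
    woolf_ci,
)
from melpanel.burden_stats import bh_adjust, burden_from_table


# --- independent oracles ---------------------------------------------------

def fisher_enumeration(t: TwoByTwo) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support:
    sum P(table) over all tables with the observed margins whose probability
    does not exceed the observed table's (with the customary 1+1e-7 slack
    for floating-point ties)."""
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, t.a) * comb(r2, c1 - t.a) / denom
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_k = comb(r1, k) * comb(r2, c1 - k) / denom
        if p_k <= p_obs * (1 + 1e-7):
            total += p_k
    return min(total, 1.0)


def chi2_hand(t: TwoByTwo) -> float:
    n = t.a + t.b + t.c + t.d
    num = n * (t.a * t.d - t.b * t.c) ** 2
    den = (t.a + t.b) * (t.c + t.d) * (t.a + t.c) * (t.b + t.d)
    return num / den


# --- odds ratio and Woolf CI -----------------------------------------------

tables_st = st.builds(
    TwoByTwo,
    a=st.integers(0, 50),
    b=st.integers(0, 50),
    c=st.integers(0, 50),
    d=st.integers(0, 50),
)


@settings(max_examples=300, derandomize=True)
@given(tables_st)
def test_odds_ratio_equals_cross_product(t):
    got = odds_ratio(t)
    if t.b * t.c == 0:
        assert math.isnan(got)
    else:
        assert got == pytest.approx((t.a * t.d) / (t.b * t.c))


@pytest.mark.parametrize(
    "table,expected",
    [
        ((9, 255, 1, 1478), 52.16),
        ((5, 5, 5, 5), 1.0),
        ((14, 75, 10, 154), 2.87),
    ],
)
def test_odds_ratio_examples(table, expected):
    assert odds_ratio(TwoByTwo(*table)) == pytest.approx(expected, abs=0.005)


def test_haldane_anscombe_correction_defines_zero_cell_or():
    t = TwoByTwo(3, 7, 0, 10)
    assert math.isnan(odds_ratio(t))
    assert odds_ratio(t, correction=True) == pytest.approx((3.5 * 10.5) / (7.5 * 0.5))


@pytest.mark.parametrize(
    "table,lo,hi",
    [
        ((22, 242, 57, 1422), 1.36, 3.78),
        ((9, 255, 1, 1478), 6.58, 413.50),
    ],
)
def test_woolf_ci_examples(table, lo, hi):
    low, high = woolf_ci(TwoByTwo(*table))
    assert low == pytest.approx(lo, abs=0.005)
    assert high == pytest.approx(hi, abs=0.005)


def test_woolf_ci_symmetric_table_contains_one():
    low, high = woolf_ci(TwoByTwo(5, 5, 5, 5))
    assert low < 1.0 < high


@settings(max_examples=200, derandomize=True)
@given(st.builds(TwoByTwo, a=st.integers(1, 40), b=st.integers(1, 40), c=st.integers(1, 40), d=st.integers(1, 40)))
def test_woolf_ci_brackets_or_and_shrinks_when_scaled(t):
    o = odds_ratio(t)
    low, high = woolf_ci(t)
    assert low <= o <= high
    scaled = TwoByTwo(3 * t.a, 3 * t.b, 3 * t.c, 3 * t.d)
    low3, high3 = woolf_ci(scaled)
    assert odds_ratio(scaled) == pytest.approx(o)
    assert math.log(high3) - math.log(low3) < math.log(high) - math.log(low)


# --- exact and chi-square tests --------------------------------------------

@pytest.mark.parametrize(
    "table,expected",
    [
        ((1, 9, 1, 9), 1.0),
        ((3, 0, 0, 3), 0.1),  # enumeration: only the two extreme tables qualify
    ],
)
def test_fisher_exact_examples(table, expected):
    assert fisher_p(TwoByTwo(*table)) == pytest.approx(expected, abs=1e-9)


def test_fisher_matches_printed_headline_p():
    assert fisher_p(TwoByTwo(22, 242, 57, 1422)) == pytest.approx(0.003, abs=0.001)


@settings(max_examples=300, derandomize=True)
@given(tables_st.filter(lambda t: 0 < t.a + t.b + t.c + t.d <= 60))
def test_fisher_equals_hypergeometric_enumeration(t):
    assert fisher_p(t) == pytest.approx(fisher_enumeration(t), rel=1e-6, abs=1e-12)


def test_chi2_examples():
    assert chi2_p(TwoByTwo(5, 5, 5, 5)) == pytest.approx(1.0)
    assert chi2_p(TwoByTwo(10, 90, 10, 90)) == pytest.approx(1.0)
    # hand formula N(ad-bc)^2 / (margin product)
    t = TwoByTwo(7, 9, 29, 135)
    assert chi2_hand(t) == pytest.approx(6.19, abs=0.005)
    from scipy.stats import chi2 as chi2_dist

    assert chi2_p(t) == pytest.approx(chi2_dist.sf(chi2_hand(t), 1))
    assert math.isnan(chi2_p(TwoByTwo(0, 0, 5, 5)))


# --- carrier profiles ------------------------------------------------------

def test_profiles_precedence_and_multiplicity(registry):
    calls = [
        ("pt1", "POT1", "chr7:1:C:T"),       # high-to-moderate
        ("pt1", "CHEK2", "chr22:1-5395:CNV:cnv_frameshifting"),  # syndrome
        ("pt2", "NBN", "chr8:2:A:G"),
        ("pt3", "FAKE_GENE", "chr1:9:A:C"),  # off-panel, excluded
    ]
    profiles = build_carrier_profiles(calls, registry)
    by_id = {p.subject_id: p for p in profiles}
    assert set(by_id) == {"pt1", "pt2"}
    assert by_id["pt1"].assigned_class is RiskClass.HIGH_MODERATE_MELANOMA
    assert by_id["pt1"].is_multi
    assert by_id["pt2"].assigned_class is RiskClass.CANCER_SYNDROME
    assert not by_id["pt2"].is_multi


def test_same_gene_double_hit_is_multi_variant_single_gene(registry):
    calls = [("pt1", "NBN", "chr8:1:A:G"), ("pt1", "NBN", "chr8:2:C:T")]
    [p] = build_carrier_profiles(calls, registry)
    assert p.is_multi and p.genes() == {"NBN"}


def _mk_profile(sid, classes, multi, gene="NBN"):
    variants = tuple((gene, f"k{i}") for i in range(2 if multi else 1))
    return CarrierProfile(
        subject_id=sid,
        plp_variants=variants,
        classes_hit=frozenset(classes),
        assigned_class=min(classes, key=lambda c: c.precedence_rank),
        is_multi=multi,
    )


def _paper_like_profiles():
    """Case profiles reproducing the class-level carrier counts of the
    264-case cohort: 9 high (1 multi), 22 syndrome (6 multi), 12 low
    (4 multi), 28 unknown; 11 multi-variant carriers in total."""
    profiles = []
    i = 0

    def add(n, classes, multi):
        nonlocal i
        for _ in range(n):
            i += 1
            profiles.append(_mk_profile(f"pt{i:03d}", classes, multi))

    add(8, [RiskClass.HIGH_MODERATE_MELANOMA], False)
    add(1, [RiskClass.HIGH_MODERATE_MELANOMA, RiskClass.CANCER_SYNDROME], True)
    add(16, [RiskClass.CANCER_SYNDROME], False)
    add(6, [RiskClass.CANCER_SYNDROME, RiskClass.UNKNOWN_MELANOMA_RISK], True)
    add(8, [RiskClass.LOW_MELANOMA], False)
    add(4, [RiskClass.LOW_MELANOMA, RiskClass.UNKNOWN_MELANOMA_RISK], True)
    add(28, [RiskClass.UNKNOWN_MELANOMA_RISK], False)
    return profiles


def _control_profiles():
    profiles = []
    counts = {
        RiskClass.HIGH_MODERATE_MELANOMA: 1,
        RiskClass.CANCER_SYNDROME: 57,
        RiskClass.LOW_MELANOMA: 35,
        RiskClass.UNKNOWN_MELANOMA_RISK: 132,
    }
    i = 0
    for cls, n in counts.items():
        for _ in range(n):
            i += 1
            profiles.append(_mk_profile(f"ct{i:04d}", [cls], False))
    return profiles


def test_class_table_reproduces_both_modes(registry):
    cases = _paper_like_profiles()
    controls = _control_profiles()
    t = class_table(cases, controls, RiskClass.HIGH_MODERATE_MELANOMA, 264, 1479, BurdenMode.INCLUDE_MULTI)
    assert (t.a, t.b, t.c, t.d) == (9, 255, 1, 1478)
    t = class_table(cases, controls, RiskClass.CANCER_SYNDROME, 264, 1479, BurdenMode.EXCLUDE_MULTI)
    assert (t.a, t.b, t.c, t.d) == (16, 237, 57, 1422)
    t = class_table(cases, controls, RiskClass.HIGH_MODERATE_MELANOMA, 264, 1479, BurdenMode.EXCLUDE_MULTI)
    assert (t.a, t.b) == (8, 245)  # 264 - 11 multis - 8 carriers


def test_include_mode_numerators_sum_to_carrier_count(registry):
    cases = _paper_like_profiles()
    controls = _control_profiles()
    total = sum(
        class_table(cases, controls, cls, 264, 1479, BurdenMode.INCLUDE_MULTI).a
        for cls in RiskClass
    )
    assert total == len(cases)


def test_class_table_zero_carriers():
    t = class_table([], [], RiskClass.LOW_MELANOMA, 10, 20, BurdenMode.INCLUDE_MULTI)
    assert (t.a, t.c) == (0, 0)


def test_class_table_invalid_mode_errors():
    with pytest.raises(ValueError, match="mode"):
        class_table([], [], RiskClass.LOW_MELANOMA, 10, 20, "bogus")


def test_gene_burden_nbn_like_counts(registry):
    """7/264 vs 4/1479 carriers gives the ~10-fold enrichment reported
    for the most frequently mutated syndrome gene."""
    cases = [_mk_profile(f"p{i}", [RiskClass.CANCER_SYNDROME], False, gene="NBN") for i in range(7)]
    controls = [_mk_profile(f"c{i}", [RiskClass.CANCER_SYNDROME], False, gene="NBN") for i in range(4)]
    r = gene_burden("NBN", cases, controls, 264, 1479, registry)
    assert r.or_point == pytest.approx(10.0, abs=0.05)
    assert r.table.a == 7 and r.table.c == 4


def test_gene_burden_zero_both_arms_and_off_panel(registry):
    r = gene_burden("NBN", [], [], 264, 1479, registry)
    assert math.isnan(r.or_point) and r.p_fisher == pytest.approx(1.0)
    with pytest.raises(ValueError, match="panel"):
        gene_burden("NOT_A_GENE", [], [], 264, 1479, registry)


def test_bh_adjust_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    ps = [0.001, 0.02, 0.03, 0.5, 0.8, 0.04]
    expected = multipletests(ps, method="fdr_bh")[1]
    assert np.allclose(bh_adjust(ps), expected)


def test_burden_result_invariant():
    r = burden_from_table("x", TwoByTwo(5, 5, 5, 5))
    assert r.ci_low <= r.or_point <= r.ci_high
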