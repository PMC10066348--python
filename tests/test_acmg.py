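"""Criterion assignment, point combination, and classification behavior."""

import random

import pytest
from hypothesis import given, strategies as st

from gynburden.acmg import (UnclassifiableVariant, assign_frequency_criteria,
                            assign_ps4, assign_pvs1, assign_remaining_criteria,
                            classify, combine, pms2_gate)
from gynburden.models import BENIGN_CRITERIA, CriterionAssignment
from gynburden.panel import Thresholds

from acmg_oracle import FIXED_STRENGTHS
from conftest import make_variant

T = Thresholds()


def _ca(criterion, strength=None):
    return CriterionAssignment(criterion, strength or FIXED_STRENGTHS[criterion])


# ---------------------------------------------------------------------------
# PVS1

@pytest.mark.parametrize("overrides, expected", [
    (dict(consequence="frameshift", nmd_predicted_by_position=True, pext=0.9),
     ("PVS1", "very_strong")),
    (dict(consequence="stop_gained", known_pathogenic_downstream=True, pext=0.9),
     ("PVS1", "very_strong")),
    (dict(consequence="stop_gained", pext=0.3), None),           # irrelevant transcript
    (dict(consequence="frameshift", pext=0.9), ("PVS1", "strong")),  # NMD escape
    (dict(consequence="missense"), None),                        # not a null variant
    (dict(consequence="canonical_splice", splice_frame_disrupted=True, pext=0.9),
     ("PVS1", "very_strong")),
    (dict(consequence="canonical_splice", splice_frame_disrupted=False, pext=0.9),
     ("PVS1", "strong")),
    (dict(consequence="start_lost", pext=0.9), ("PVS1", "strong")),
])
def test_pvs1_decision_tree(panel, overrides, expected):
    got, flag = assign_pvs1(make_variant(**overrides), panel.profile("BRCA1"), T)
    assert flag is False
    if expected is None:
        assert got is None
    else:
        assert (got.criterion, got.strength) == expected


def test_pvs1_requires_haploinsufficient_gene(panel):
    from dataclasses import replace
    profile = replace(panel.profile("BRCA1"), haploinsufficient=False)
    got, flag = assign_pvs1(
        make_variant(consequence="frameshift", nmd_predicted_by_position=True),
        profile, T)
    assert got is None and flag is False


def test_pvs1_unassessable_splice_forces_vus(panel):
    v = make_variant(consequence="canonical_splice", pext=0.9,
                     splice_frame_disrupted=None)
    got, flag = assign_pvs1(v, panel.profile("BRCA1"), T)
    assert got is None and flag is True
    cv = classify(v, panel.profile("BRCA1"), T)
    assert cv.classification == "vus"
    assert any(a["rule"] == "pvs1_unassessable_override" for a in cv.audit)


# ---------------------------------------------------------------------------
# PS4

@pytest.mark.parametrize("overrides, expected", [
    (dict(gnomad_af=2e-5, lit_case_control_or=6.0), ("PS4", "strong")),
    (dict(gnomad_af=2e-5, lit_case_control_or=4.0), None),
    (dict(gnomad_af=2e-5, lit_patient_count=9), None),  # common branch ignores counts
    (dict(gnomad_af=5e-6, lit_patient_count=5), ("PS4", "strong")),
    (dict(gnomad_af=5e-6, lit_patient_count=3), ("PS4", "moderate")),
    (dict(gnomad_af=5e-6, lit_patient_count=2), ("PS4", "supporting")),
    (dict(gnomad_af=5e-6, lit_patient_count=1), None),
    # the 0.001% boundary itself uses the case-control branch
    (dict(gnomad_af=1e-5, lit_patient_count=9), None),
    (dict(gnomad_af=1e-5, lit_case_control_or=6.0), ("PS4", "strong")),
])
def test_ps4_tiering(overrides, expected):
    got = assign_ps4(make_variant(**overrides), T)
    if expected is None:
        assert got is None
    else:
        assert (got.criterion, got.strength) == expected


# ---------------------------------------------------------------------------
# frequency criteria

@pytest.mark.parametrize("af, expected", [
    (0.0, {"PM2"}),
    (1e-5, {"PM2"}),
    (2e-5, {"PM2"}),
    (5e-5, set()),          # between PM2 rarity and the BS1 cutoff
    (0.01, {"BS1"}),
    (0.06, {"BA1"}),
    (0.05, {"BA1"}),        # BA1 is inclusive at 5%
])
def test_frequency_criteria(panel, af, expected):
    got = assign_frequency_criteria(
        make_variant(gnomad_af=af,
                     gnomad_het_count=int(af * 2 * 134187)),
        panel.profile("BRCA1"), T)
    assert {c.criterion for c in got} == expected
    assert len(got) <= 1  # BA1/BS1/PM2 mutually exclusive


def test_bs1_uses_gene_specific_cutoff(panel):
    # af above BRCA1's cutoff but below CHEK2's
    v = make_variant(gnomad_af=1e-3, gnomad_het_count=268)
    assert {c.criterion for c in
            assign_frequency_criteria(v, panel.profile("BRCA1"), T)} == {"BS1"}
    assert assign_frequency_criteria(v, panel.profile("CHEK2"), T) == []


# ---------------------------------------------------------------------------
# remaining criteria

@pytest.mark.parametrize("gene, overrides, expected", [
    ("TP53", dict(in_functional_domain=True), {"PP2", "PM1"}),  # z 3.6 > 3.09
    ("BRCA1", dict(in_functional_domain=True), {"PM1"}),        # z below cutoff
    ("BRCA1", dict(consequence="inframe_indel", in_repeat_region=True), {"BP3"}),
    ("BRCA1", dict(consequence="inframe_indel"), {"PM4"}),
    ("BRCA1", dict(consequence="stop_lost"), {"PM4"}),
    ("BRCA1", dict(consequence="stop_lost", in_repeat_region=True), set()),
    ("BRCA1", dict(consequence="synonymous", phastcons=0.05), {"BP7"}),
    ("BRCA1", dict(consequence="synonymous", phastcons=0.05, hsf_splice_impact=True),
     set()),
    ("BRCA1", dict(consequence="synonymous", phastcons=0.5), set()),
    ("BRCA1", dict(clinvar_same_aa_pathogenic=True), {"PS1"}),
    ("BRCA1", dict(clinvar_other_aa_change_pathogenic=True), {"PM5"}),
    ("BRCA1", dict(clinvar_same_aa_pathogenic=True,
                   clinvar_other_aa_change_pathogenic=True), {"PS1"}),
    ("BRCA1", dict(lit_functional="damaging"), {"PS3"}),
    ("BRCA1", dict(lit_functional="benign_effect"), {"BS3"}),
    ("BRCA1", dict(lit_segregation="cosegregates"), {"PP1"}),
    ("BRCA1", dict(lit_segregation="does_not_segregate"), {"BS4"}),
    ("BRCA1", dict(in_silico_consensus="pathogenic"), {"PP3"}),
    ("BRCA1", dict(in_silico_consensus="benign"), {"BP4"}),
    ("BRCA1", dict(in_silico_consensus="mixed"), set()),
])
def test_remaining_criteria(panel, gene, overrides, expected):
    got = assign_remaining_criteria(make_variant(gene=gene, **overrides),
                                    panel.profile(gene), T)
    assert {c.criterion for c in got} == expected


def test_pms2_gate():
    assert pms2_gate(make_variant(gene="PMS2", pms2_unique_region=True))
    assert not pms2_gate(make_variant(gene="PMS2", pms2_unique_region=False))
    assert pms2_gate(make_variant(gene="MLH1", pms2_unique_region=False))


# ---------------------------------------------------------------------------
# combination

@pytest.mark.parametrize("names, points, tier", [
    (["PVS1", "PM2"], 9, "likely_pathogenic"),   # very strong + supporting
    (["PVS1", "PM5"], 10, "pathogenic"),         # very strong + moderate
    (["PS3", "PS4"], 8, "likely_pathogenic"),    # two strong
    ([], 0, "vus"),
    (["PM2"], 1, "vus"),
    (["PVS1"], 8, "likely_pathogenic"),
    (["BS1", "BS3"], -8, "benign"),
    (["BS1", "BP4"], -5, "likely_benign"),
    (["PVS1", "PS3", "PM1", "PM2"], 15, "pathogenic"),
])
def test_combine_point_scale(names, points, tier):
    got_points, got_tier = combine([_ca(n) for n in names])
    assert (got_points, got_tier) == (points, tier)


def test_ba1_short_circuits_everything():
    _, tier = combine([_ca("BA1"), _ca("PVS1"), _ca("PS3"), _ca("PM1")])
    assert tier == "benign"


def test_duplicate_criterion_rejected():
    with pytest.raises(ValueError, match="more than once"):
        combine([_ca("PM2"), _ca("PM2")])


@given(st.sets(st.sampled_from(sorted(FIXED_STRENGTHS)), max_size=6),
       st.sampled_from(sorted(set(FIXED_STRENGTHS) - BENIGN_CRITERIA)),
       st.randoms(use_true_random=False))
def test_combine_monotone_and_order_independent(names, extra, rnd):
    """Adding pathogenic evidence never lowers points or the class, and the
    result is invariant under permutation of the assignment order."""
    crits = [_ca(n) for n in names]
    pts, tier = combine(crits)
    shuffled = list(crits)
    rnd.shuffle(shuffled)
    assert combine(shuffled) == (pts, tier)
    if extra not in names:
        pts2, tier2 = combine(crits + [_ca(extra)])
        assert pts2 >= pts
        order = ["benign", "likely_benign", "vus", "likely_pathogenic", "pathogenic"]
        if "BA1" not in names:  # BA1 short-circuit is exempt from monotonicity
            assert order.index(tier2) >= order.index(tier)


# ---------------------------------------------------------------------------
# classify

def test_classify_plp_regime(panel):
    """An NMD-predicted null in a haploinsufficient gene, absent from gnomAD,
    reaches at least likely pathogenic."""
    v = make_variant(consequence="frameshift", nmd_predicted_by_position=True)
    cv = classify(v, panel.profile("BRCA1"), T)
    assert cv.classification == "likely_pathogenic"
    assert {c.criterion for c in cv.criteria} == {"PVS1", "PM2"}
    assert cv.points == 9


def test_classify_no_evidence_is_vus(panel):
    v = make_variant(gnomad_af=5e-5, gnomad_het_count=13)
    cv = classify(v, panel.profile("BRCA1"), T)
    assert cv.criteria == () and cv.classification == "vus"


def test_classify_bypass_records_tension(panel):
    """A known-pathogenic but frequent variant is classified on points and
    the audit records its bypass provenance."""
    v = make_variant(consequence="frameshift", nmd_predicted_by_position=True,
                     clinvar_status="pathogenic_multiple_unanimous",
                     gnomad_af=1.2e-3, gnomad_het_count=320,
                     lit_case_control_or=8.0, lit_functional="damaging")
    cv = classify(v, panel.profile("BRCA1"), T, bypass=True)
    assert cv.audit[0]["rule"] == "prefilter_bypass"
    assert {c.criterion for c in cv.criteria} >= {"PVS1", "PS3", "PS4", "BS1"}
    assert cv.classification == "pathogenic"  # 8+4+4-4 = 12


def test_classify_missing_mandatory_field_names_it(panel):
    v = make_variant()
    v.pext = None
    with pytest.raises(UnclassifiableVariant, match="pext"):
        classify(v, panel.profile("BRCA1"), T)


def test_points_equal_criterion_sum_property(panel):
    """Classification invariants on a mixed bag of variants: points always
    equal the signed sum of the criterion values."""
    from gynburden.acmg import BENIGN_POINTS, PATHOGENIC_POINTS
    rnd = random.Random(7)
    for _ in range(50):
        v = make_variant(
            consequence=rnd.choice(["missense", "frameshift", "synonymous",
                                    "inframe_indel"]),
            gnomad_af=rnd.choice([0.0, 5e-6, 5e-5, 1e-3]),
            lit_functional=rnd.choice(["none", "damaging", "benign_effect"]),
            in_functional_domain=rnd.random() < 0.5,
            nmd_predicted_by_position=rnd.random() < 0.5,
        )
        cv = classify(v, panel.profile("BRCA1"), T)
        total = sum(-BENIGN_POINTS[c.strength] if c.criterion in BENIGN_CRITERIA
                    else PATHOGENIC_POINTS[c.strength]
                    for c in cv.criteria if c.criterion != "BA1")
        assert cv.points == total
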