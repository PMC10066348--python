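"""Prefilter cascade: predicates, boundaries, bypass, and set properties."""

import pytest
from hypothesis import given, strategies as st

from gynburden.models import CONSEQUENCES, MODERATE_HIGH_IMPACT
from gynburden.prefilter import (is_known_pathogenic, passes_clinvar_filter,
                                 passes_effect_filter, passes_frequency_filter,
                                 run_prefilter)

from conftest import make_variant


@pytest.mark.parametrize("overrides, expected", [
    # moderate/high impact list membership
    (dict(consequence="frameshift"), True),
    (dict(consequence="utr_deletion"), True),
    (dict(consequence="inframe_indel"), True),
    (dict(consequence="noncoding"), False),
    (dict(consequence="other"), False),
    # splice rescue is strictly > 0.5, absent scores count as 0
    (dict(consequence="synonymous", splice_ada=0.8), True),
    (dict(consequence="synonymous", splice_ada=0.51), True),
    (dict(consequence="synonymous", splice_ada=0.5, splice_rf=0.5), False),
    (dict(consequence="synonymous"), False),
    (dict(consequence="noncoding", splice_rf=0.9), True),
])
def test_effect_filter(overrides, expected):
    assert passes_effect_filter(make_variant(**overrides)) is expected


@pytest.mark.parametrize("overrides, expected", [
    # all cutoffs are inclusive: exclusion only strictly above them
    (dict(gnomad_het_count=10, local_carrier_count=20,
          gnomad_hom_count=3, local_hom_count=3), True),
    (dict(gnomad_het_count=11), False),
    (dict(local_carrier_count=21), False),
    (dict(gnomad_hom_count=4), False),
    (dict(local_hom_count=4), False),
])
def test_frequency_filter_boundaries(overrides, expected):
    assert passes_frequency_filter(make_variant(**overrides)) is expected


@pytest.mark.parametrize("overrides, expected", [
    (dict(clinvar_status="likely_benign"), False),
    (dict(clinvar_status="benign"), False),
    (dict(clinvar_status="conflicting_blb_vus"), False),
    (dict(clinvar_status="absent"), True),
    (dict(clinvar_status="vus"), True),
    # low-impact variants need ClinVar support or a splice signal
    (dict(consequence="synonymous", splice_ada=0.2, clinvar_status="absent"), False),
    (dict(consequence="noncoding", clinvar_status="vus"), False),
    (dict(consequence="synonymous", splice_ada=0.8, clinvar_status="absent"), True),
    (dict(consequence="synonymous", clinvar_status="pathogenic"), True),
])
def test_clinvar_filter(overrides, expected):
    assert passes_clinvar_filter(make_variant(**overrides)) is expected


def test_known_pathogenic_requires_multiple_unanimous():
    assert is_known_pathogenic(make_variant(clinvar_status="pathogenic_multiple_unanimous"))
    assert not is_known_pathogenic(make_variant(clinvar_status="pathogenic"))
    assert not is_known_pathogenic(make_variant(clinvar_status="vus"))


def test_bypass_dominates_all_filters():
    """A known pathogenic variant failing effect AND frequency is kept."""
    v = make_variant(consequence="other", gnomad_het_count=300,
                     clinvar_status="pathogenic_multiple_unanimous")
    retained, decisions, cascade = run_prefilter([v])
    assert [d.stage for d in decisions] == ["bypass"]
    assert retained == [v]
    assert cascade["bypass"] == 1


def test_cascade_hand_enumerated_fixture():
    """10 variants, 3 too frequent in gnomAD: 7 retained."""
    variants = [make_variant(variant_id=f"17:{i}:G:A") for i in range(7)]
    variants += [make_variant(variant_id=f"17:{100+i}:G:A", gnomad_het_count=50)
                 for i in range(3)]
    retained, decisions, cascade = run_prefilter(variants)
    assert len(retained) == 7
    assert cascade == {"input": 10, "excluded_effect": 0, "excluded_frequency": 3,
                       "excluded_clinvar": 0, "bypass": 0,
                       "retained_without_bypass": 7, "retained": 7}


def test_empty_input():
    retained, decisions, cascade = run_prefilter([])
    assert retained == [] and decisions == []
    assert cascade["input"] == 0 and cascade["retained"] == 0


def test_duplicate_variant_id_rejected():
    v = make_variant()
    with pytest.raises(ValueError, match="duplicate variant_id"):
        run_prefilter([v, make_variant()])


def test_negative_count_rejected():
    v = make_variant()
    object.__setattr__(v, "gnomad_het_count", -1)
    with pytest.raises(ValueError, match="gnomad_het_count"):
        passes_frequency_filter(v)


@st.composite
def variants(draw):
    return make_variant(
        variant_id=f"17:{draw(st.integers(1, 10**6))}:G:A",
        consequence=draw(st.sampled_from(sorted(CONSEQUENCES))),
        splice_ada=draw(st.one_of(st.none(), st.floats(0, 1))),
        splice_rf=draw(st.one_of(st.none(), st.floats(0, 1))),
        gnomad_het_count=draw(st.integers(0, 40)),
        gnomad_hom_count=draw(st.integers(0, 8)),
        local_carrier_count=draw(st.integers(0, 40)),
        local_hom_count=draw(st.integers(0, 8)),
        clinvar_status=draw(st.sampled_from([
            "pathogenic_multiple_unanimous", "pathogenic", "likely_pathogenic",
            "vus", "conflicting_blb_vus", "likely_benign", "benign", "absent"])),
    )


@given(variants())
def test_partition_and_bypass_dominance(v):
    """Every variant lands in exactly one bucket; known pathogenic is always
    retained; otherwise retention equals the conjunction of the three
    predicates regardless of evaluation order."""
    retained, decisions, cascade = run_prefilter([v])
    assert len(decisions) == 1
    expected = is_known_pathogenic(v) or (
        passes_effect_filter(v) and passes_frequency_filter(v)
        and passes_clinvar_filter(v))
    assert (len(retained) == 1) == expected == decisions[0].retained
    assert cascade["retained"] + sum(
        cascade[f"excluded_{s}"] for s in ("effect", "frequency", "clinvar")
    ) == cascade["input"]


@given(variants(), st.integers(0, 40), st.integers(0, 8), st.integers(0, 40),
       st.integers(0, 8))
def test_frequency_monotonicity(v, het, ghom, local, lhom):
    """Decreasing any frequency count never flips retained to excluded."""
    lower = make_variant(**{**{f.name: getattr(v, f.name)
                               for f in v.__dataclass_fields__.values()
                               if f.name != "extras"},
                            "gnomad_het_count": min(het, v.gnomad_het_count),
                            "gnomad_hom_count": min(ghom, v.gnomad_hom_count),
                            "local_carrier_count": min(local, v.local_carrier_count),
                            "local_hom_count": min(lhom, v.local_hom_count)})
    retained_hi, _, _ = run_prefilter([v])
    retained_lo, _, _ = run_prefilter([lower])
    if retained_hi:
        assert retained_lo
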