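"""ACMG/AMP evidence assignment and point-based combination.

Criteria are assigned from annotation fields at the strengths this pipeline
fixes (PM2 always supporting; PS4 tiered strong/moderate/supporting; BA1
stand-alone) and combined on the Bayesian point scale: very strong = 8,
strong = 4, moderate = 2, supporting = 1 on the pathogenic side; strong = 4
and supporting = 1 subtracted on the benign side. Totals map to the five
tiers as

    pathogenic        >= 10
    likely pathogenic   6 .. 9
    VUS                 0 .. 5
    likely benign      -6 .. -1
    benign            <= -7

with BA1 short-circuiting to benign regardless of other evidence. The scale
reproduces the amendments this pipeline pins: a very strong plus a moderate
criterion reaches pathogenic (8+2), two strong criteria reach likely
pathogenic (4+4), and PVS1 with PM2 at supporting strength alone is likely
pathogenic (8+1).

PVS1 follows the ClinGen loss-of-function decision tree restricted to the
fields available here: the gene must be haploinsufficient, the variant must
land in a biologically relevant transcript (exon pext > 0.5), and the
strength is very strong when nonsense-mediated decay is predicted (stop 5'
of the last 50 nt of the penultimate exon, or known pathogenic variants
downstream) and strong for NMD-escaping nulls. Canonical splice variants
substitute reading-frame disruption for the NMD position rule; if frame
impact was not assessed the evidence is unassessable and the variant is
forced to VUS.
"""

from __future__ import annotations

from typing import Optional

from .models import (
    AnnotatedVariant,
    BENIGN_CRITERIA,
    ClassifiedVariant,
    CriterionAssignment,
    GeneProfile,
)
from .panel import Thresholds

PATHOGENIC_POINTS = {"very_strong": 8, "strong": 4, "moderate": 2, "supporting": 1}
BENIGN_POINTS = {"strong": 4, "supporting": 1}

#: Annotation fields classify() requires to be present (not None).
MANDATORY_FIELDS = (
    "consequence", "gnomad_af", "clinvar_status", "pext", "phastcons",
    "lit_functional", "lit_segregation", "in_silico_consensus",
)


class UnclassifiableVariant(ValueError):
    """Raised when a mandatory annotation field is missing."""

    def __init__(self, variant_id: str, field_name: str):
        self.variant_id = variant_id
        self.field = field_name
        super().__init__(
            f"variant {variant_id} cannot be classified: "
            f"mandatory field {field_name!r} is missing"
        )


def assign_pvs1(
    v: AnnotatedVariant, g: GeneProfile, t: Thresholds = Thresholds()
) -> tuple[Optional[CriterionAssignment], bool]:
    """Loss-of-function evidence; returns (assignment, unassessable_flag).

    ``unassessable_flag`` is set for a canonical splice variant in a
    haploinsufficient gene whose frame impact was never assessed — the one
    situation where the decision tree cannot be evaluated at all.
    """
    if not g.haploinsufficient:
        return None, False
    if v.consequence not in ("frameshift", "stop_gained", "canonical_splice", "start_lost"):
        return None, False
    if v.pext <= t.pext_min:
        # not in a biologically relevant transcript: no LoF evidence
        return None, False
    if v.consequence == "canonical_splice":
        if v.splice_frame_disrupted is None:
            return None, True
        if v.splice_frame_disrupted:
            return CriterionAssignment(
                "PVS1", "very_strong",
                "canonical splice site, reading frame disrupted"), False
        return CriterionAssignment(
            "PVS1", "strong",
            "canonical splice site, reading frame preserved"), False
    if v.consequence in ("frameshift", "stop_gained"):
        if v.nmd_predicted_by_position or v.known_pathogenic_downstream:
            return CriterionAssignment(
                "PVS1", "very_strong",
                "null variant predicted to undergo nonsense-mediated decay"), False
        return CriterionAssignment(
            "PVS1", "strong",
            "NMD-escaping null in a biologically relevant exon"), False
    # start_lost: no NMD position rule applies; treated like an NMD-escaping null
    return CriterionAssignment("PVS1", "strong", "start-loss null variant"), False


def assign_ps4(
    v: AnnotatedVariant, t: Thresholds = Thresholds()
) -> Optional[CriterionAssignment]:
    """Case-control / case-count evidence, tiered by gnomAD frequency.

    Variants at or above 0.001% gnomAD frequency need a reported
    case-control OR > 5 for PS4 at strong; rarer variants are tiered by the
    number of previously reported patients (>4 strong, >2 moderate,
    >1 supporting). Equality with the frequency cutoff uses the
    case-control branch.
    """
    if v.gnomad_af >= t.ps4_common_af:
        if v.lit_case_control_or is not None and v.lit_case_control_or > t.ps4_or_min:
            return CriterionAssignment(
                "PS4", "strong",
                f"case-control OR {v.lit_case_control_or:g} > {t.ps4_or_min:g}")
        return None
    n = v.lit_patient_count
    if n > t.ps4_patients_strong:
        return CriterionAssignment("PS4", "strong", f"{n} patients reported")
    if n > t.ps4_patients_moderate:
        return CriterionAssignment("PS4", "moderate", f"{n} patients reported")
    if n > t.ps4_patients_supporting:
        return CriterionAssignment("PS4", "supporting", f"{n} patients reported")
    return None


def assign_frequency_criteria(
    v: AnnotatedVariant, g: GeneProfile, t: Thresholds = Thresholds()
) -> list[CriterionAssignment]:
    """BA1 / BS1 / PM2 from the gnomAD allele frequency; mutually exclusive."""
    af = v.gnomad_af
    if af >= t.ba1_af:
        return [CriterionAssignment("BA1", "stand_alone",
                                    f"gnomAD af {af:g} >= {t.ba1_af:g}")]
    if af > g.bs1_cutoff:
        return [CriterionAssignment("BS1", "strong",
                                    f"gnomAD af {af:g} > gene cutoff {g.bs1_cutoff:g}")]
    absent = v.gnomad_af == 0 and v.gnomad_het_count == 0 and v.gnomad_hom_count == 0
    if absent or af <= t.pm2_af_max:
        why = "absent from gnomAD" if absent else f"gnomAD af {af:g} <= {t.pm2_af_max:g}"
        return [CriterionAssignment("PM2", "supporting", why)]
    return []


def assign_remaining_criteria(
    v: AnnotatedVariant, g: GeneProfile, t: Thresholds = Thresholds()
) -> list[CriterionAssignment]:
    """All criteria outside PVS1/PS4/frequency, in a fixed audit order."""
    out: list[CriterionAssignment] = []
    if v.clinvar_same_aa_pathogenic:
        out.append(CriterionAssignment(
            "PS1", "strong", "same amino-acid change previously established pathogenic"))
    elif v.clinvar_other_aa_change_pathogenic:
        out.append(CriterionAssignment(
            "PM5", "moderate", "different pathogenic missense change at the same residue"))
    if v.lit_functional == "damaging":
        out.append(CriterionAssignment("PS3", "strong", "functional studies show damage"))
    elif v.lit_functional == "benign_effect":
        out.append(CriterionAssignment("BS3", "strong", "functional studies show no damage"))
    if v.consequence == "missense" and v.in_functional_domain:
        out.append(CriterionAssignment("PM1", "moderate", "missense in a functional domain"))
    if v.consequence in ("inframe_indel", "stop_lost"):
        if v.in_repeat_region and v.consequence == "inframe_indel":
            out.append(CriterionAssignment("BP3", "supporting",
                                           "in-frame indel within a repeat region"))
        elif not v.in_repeat_region:
            out.append(CriterionAssignment("PM4", "moderate",
                                           "protein-length change outside a repeat region"))
    if v.lit_segregation == "cosegregates":
        out.append(CriterionAssignment("PP1", "supporting", "cosegregates with disease"))
    elif v.lit_segregation == "does_not_segregate":
        out.append(CriterionAssignment("BS4", "strong", "lack of segregation in affected"))
    if v.consequence == "missense" and g.z_score > t.pp2_z_min:
        out.append(CriterionAssignment(
            "PP2", "supporting",
            f"missense in constrained gene (z {g.z_score:g} > {t.pp2_z_min:g})"))
    if v.in_silico_consensus == "pathogenic":
        out.append(CriterionAssignment("PP3", "supporting",
                                       "in-silico consensus predicts damage"))
    elif v.in_silico_consensus == "benign":
        out.append(CriterionAssignment("BP4", "supporting",
                                       "in-silico consensus predicts no damage"))
    if (v.consequence == "synonymous" and v.phastcons < t.bp7_phastcons_max
            and not v.hsf_splice_impact):
        out.append(CriterionAssignment("BP7", "supporting",
                                       "non-conserved synonymous, no splice impact"))
    return out


def pms2_gate(v: AnnotatedVariant) -> bool:
    """PMS2 variants are only interpretable in the pseudogene-free region.

    Returns False (drop from classification and burden) for PMS2 variants
    outside the unique region; True for everything else.
    """
    if v.gene == "PMS2" and not v.pms2_unique_region:
        return False
    return True


def combine(criteria: tuple[CriterionAssignment, ...] | list[CriterionAssignment]
            ) -> tuple[int, str]:
    """Sum evidence points and map to the five-tier classification.

    BA1 forces benign regardless of other evidence; it contributes no points.
    """
    seen = set()
    for c in criteria:
        if c.criterion in seen:
            raise ValueError(f"criterion {c.criterion} applied more than once")
        seen.add(c.criterion)

    points = 0
    ba1 = False
    for c in criteria:
        if c.criterion == "BA1":
            ba1 = True
        elif c.criterion in BENIGN_CRITERIA:
            points -= BENIGN_POINTS[c.strength]
        else:
            points += PATHOGENIC_POINTS[c.strength]
    if ba1:
        return points, "benign"
    if points >= 10:
        tier = "pathogenic"
    elif points >= 6:
        tier = "likely_pathogenic"
    elif points >= 0:
        tier = "vus"
    elif points >= -6:
        tier = "likely_benign"
    else:
        tier = "benign"
    return points, tier


def classify(
    v: AnnotatedVariant,
    g: GeneProfile,
    t: Thresholds = Thresholds(),
    bypass: bool = False,
) -> ClassifiedVariant:
    """Run every assignment rule, combine, and record the audit trail.

    ``bypass=True`` marks a variant that reached classification through the
    known-pathogenic prefilter bypass; the provenance is recorded in the
    audit but contributes no evidence weight.
    """
    for name in MANDATORY_FIELDS:
        if getattr(v, name, None) is None:
            raise UnclassifiableVariant(v.variant_id, name)

    audit: list[dict] = []
    criteria: list[CriterionAssignment] = []
    if bypass:
        audit.append({"rule": "prefilter_bypass",
                      "outcome": "classified on assigned criteria only",
                      "detail": "known pathogenic in ClinVar; consensus itself "
                                "carries no evidence weight here"})

    pvs1, unassessable = assign_pvs1(v, g, t)
    audit.append({"rule": "PVS1", "outcome": pvs1.label if pvs1 else "not applied",
                  "detail": pvs1.rationale if pvs1 else
                  ("frame impact unassessed" if unassessable else "gate not met")})
    if pvs1:
        criteria.append(pvs1)

    ps4 = assign_ps4(v, t)
    audit.append({"rule": "PS4", "outcome": ps4.label if ps4 else "not applied",
                  "detail": ps4.rationale if ps4 else ""})
    if ps4:
        criteria.append(ps4)

    freq = assign_frequency_criteria(v, g, t)
    audit.append({"rule": "frequency(BA1/BS1/PM2)",
                  "outcome": ";".join(c.label for c in freq) or "not applied",
                  "detail": "; ".join(c.rationale for c in freq)})
    criteria.extend(freq)

    rest = assign_remaining_criteria(v, g, t)
    audit.append({"rule": "remaining criteria",
                  "outcome": ";".join(c.label for c in rest) or "none",
                  "detail": "; ".join(c.rationale for c in rest)})
    criteria.extend(rest)

    points, tier = combine(criteria)
    if unassessable:
        audit.append({"rule": "pvs1_unassessable_override", "outcome": "vus",
                      "detail": "canonical splice variant without frame assessment; "
                                "classification forced to VUS"})
        tier = "vus"
    audit.append({"rule": "combine", "outcome": tier, "detail": f"{points} points"})

    return ClassifiedVariant(
        variant_id=v.variant_id,
        gene=v.gene,
        criteria=tuple(criteria),
        points=points,
        classification=tier,
        audit=tuple(audit),
    )
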