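"""Three-stage variant prefilter with the known-pathogenic bypass.

Candidate variants for classification must (1) have a moderate/high
predicted impact on the protein or a high splice-disruption score,
(2) be rare in both gnomAD and the local cohort, and (3) not carry a
benign-leaning ClinVar consensus. Known pathogenic variants — multiple
unanimous pathogenic ClinVar submissions — bypass the effect and frequency
stages entirely.

The retained set is order-independent; the stage recorded on an excluded
variant follows the fixed audit order effect → frequency → ClinVar.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .models import AnnotatedVariant, FilterDecision, MODERATE_HIGH_IMPACT
from .panel import Thresholds


def passes_effect_filter(v: AnnotatedVariant, t: Thresholds = Thresholds()) -> bool:
    """Moderate/high protein impact, or splice score above the rescue cutoff.

    Absent splice scores count as 0, so an unscored synonymous variant is
    never rescued.
    """
    if v.consequence in MODERATE_HIGH_IMPACT:
        return True
    return v.max_splice_score > t.splice_score_min


def passes_frequency_filter(v: AnnotatedVariant, t: Thresholds = Thresholds()) -> bool:
    """Rare in gnomAD and the local cohort; exclusion is strictly '>' at
    every cutoff (10 gnomAD heterozygotes, 20 local carriers, 3 homozygotes
    in either population are all still retained)."""
    for name in ("gnomad_het_count", "gnomad_hom_count",
                 "local_carrier_count", "local_hom_count"):
        if getattr(v, name) < 0:
            raise ValueError(f"{name} is negative for {v.variant_id}")
    return (v.gnomad_het_count <= t.gnomad_het_max
            and v.local_carrier_count <= t.local_carrier_max
            and v.gnomad_hom_count <= t.gnomad_hom_max
            and v.local_hom_count <= t.local_hom_max)


def passes_clinvar_filter(v: AnnotatedVariant, t: Thresholds = Thresholds()) -> bool:
    """Drop benign-leaning ClinVar consensus, and low-impact variants with no
    supportive ClinVar record.

    Excluded: benign, likely benign, or B/LB-vs-VUS conflicts; additionally,
    noncoding and synonymous variants not predicted to affect splicing that
    are absent from ClinVar or recorded as VUS. P/LP-vs-VUS conflicts are not
    modeled as exclusions and remain candidates.
    """
    if v.clinvar_status in ("benign", "likely_benign", "conflicting_blb_vus"):
        return False
    if (v.consequence in ("noncoding", "synonymous")
            and v.max_splice_score <= t.splice_score_min
            and v.clinvar_status in ("absent", "vus")):
        return False
    return True


def is_known_pathogenic(v: AnnotatedVariant) -> bool:
    """Multiple unanimous pathogenic ClinVar submissions."""
    return v.clinvar_status == "pathogenic_multiple_unanimous"


def run_prefilter(
    variants: Sequence[AnnotatedVariant],
    t: Thresholds = Thresholds(),
) -> tuple[list[AnnotatedVariant], list[FilterDecision], dict]:
    """Apply the cascade to a variant list.

    Returns the retained variants, one :class:`FilterDecision` per input,
    and the cascade counts. ``retained_without_bypass`` counts variants that
    pass all three filters on their own; ``bypass`` counts known-pathogenic
    variants kept despite failing at least one filter; ``retained`` is their
    sum, and input = retained + excluded stages.
    """
    ids = Counter(v.variant_id for v in variants)
    dupes = [vid for vid, n in ids.items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate variant_id(s): {', '.join(sorted(dupes))}")

    retained: list[AnnotatedVariant] = []
    decisions: list[FilterDecision] = []
    counts = Counter()
    counts["input"] = len(variants)
    for v in variants:
        ok_effect = passes_effect_filter(v, t)
        ok_freq = passes_frequency_filter(v, t)
        ok_clinvar = passes_clinvar_filter(v, t)
        if ok_effect and ok_freq and ok_clinvar:
            decisions.append(FilterDecision(v.variant_id, True, "retained",
                                            "passes effect, frequency and ClinVar filters"))
            retained.append(v)
            counts["retained_without_bypass"] += 1
        elif is_known_pathogenic(v):
            failed = [name for name, ok in
                      (("effect", ok_effect), ("frequency", ok_freq), ("clinvar", ok_clinvar))
                      if not ok]
            decisions.append(FilterDecision(
                v.variant_id, True, "bypass",
                "known pathogenic (multiple unanimous ClinVar submissions); "
                f"bypasses failed filter(s): {', '.join(failed)}"))
            retained.append(v)
            counts["bypass"] += 1
        else:
            if not ok_effect:
                stage, why = "effect", "no moderate/high impact and no splice rescue"
            elif not ok_freq:
                stage, why = "frequency", "too frequent in gnomAD or the local cohort"
            else:
                stage, why = "clinvar", "benign-leaning or unsupported ClinVar status"
            decisions.append(FilterDecision(v.variant_id, False, stage, why))
            counts[f"excluded_{stage}"] += 1

    counts["retained"] = counts["retained_without_bypass"] + counts["bypass"]
    cascade = {key: counts.get(key, 0) for key in
               ("input", "excluded_effect", "excluded_frequency", "excluded_clinvar",
                "bypass", "retained_without_bypass", "retained")}
    return retained, decisions, cascade
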