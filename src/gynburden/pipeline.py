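"""End-to-end orchestration: prefilter → classification → burden table.

Deterministic for fixed inputs; the audit JSON records the filter cascade,
per-variant criteria, every effective threshold, PMS2 homology drops and
unclassifiable variants — full provenance for one run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__ as _version
from .acmg import UnclassifiableVariant, classify, pms2_gate
from .burden import build_burden_table, count_carriers
from .models import (AnnotatedVariant, BurdenRow, ClassifiedVariant,
                     CohortSummary, ControlSummary, FilterDecision)
from .panel import PanelConfig, default_panel
from .prefilter import run_prefilter


@dataclass
class PipelineResult:
    classified: list[ClassifiedVariant]
    decisions: list[FilterDecision]
    cascade: dict
    summary: CohortSummary
    burden: list[BurdenRow]
    pms2_dropped: list[str]
    unclassifiable: list[dict]
    audit: dict = field(default_factory=dict)


def classify_retained(
    retained: Sequence[AnnotatedVariant],
    panel: PanelConfig,
    bypass_ids: frozenset[str] = frozenset(),
) -> tuple[list[ClassifiedVariant], list[str], list[dict]]:
    """Classify prefilter survivors, applying the PMS2 homology gate first.

    Returns (classified, pms2-dropped ids, unclassifiable records).
    """
    classified: list[ClassifiedVariant] = []
    dropped: list[str] = []
    unclassifiable: list[dict] = []
    for v in retained:
        if not pms2_gate(v):
            dropped.append(v.variant_id)
            continue
        try:
            cv = classify(v, panel.profile(v.gene), panel.thresholds,
                          bypass=v.variant_id in bypass_ids)
        except UnclassifiableVariant as err:
            unclassifiable.append({"variant_id": err.variant_id, "field": err.field})
            continue
        classified.append(cv)
    return classified, dropped, unclassifiable


def run_pipeline(
    variants: Sequence[AnnotatedVariant],
    control: ControlSummary,
    cohort_size: int,
    panel: Optional[PanelConfig] = None,
) -> PipelineResult:
    """Run the full analysis over an annotated variant table."""
    panel = panel or default_panel()
    unknown = sorted({v.gene for v in variants} - set(panel.genes))
    if unknown:
        raise ValueError(f"variant table names non-panel gene(s): {', '.join(unknown)}")

    retained, decisions, cascade = run_prefilter(variants, panel.thresholds)
    bypass_ids = frozenset(d.variant_id for d in decisions if d.stage == "bypass")
    classified, dropped, unclassifiable = classify_retained(retained, panel, bypass_ids)

    genotypes = {v.variant_id: v.carrier_ids for v in variants
                 if v.variant_id in {c.variant_id for c in classified}}
    summary = count_carriers(classified, genotypes, cohort_size, panel.genes)
    burden = build_burden_table(summary, control, panel.genes,
                                yates=panel.thresholds.yates_correction)

    audit = {
        "tool": {"name": "gynburden", "version": _version},
        "cohort_size": cohort_size,
        "control_size": control.n_individuals,
        "cascade": cascade,
        "pms2_homology_dropped": dropped,
        "unclassifiable": unclassifiable,
        "effective_thresholds": panel.effective_thresholds(),
        "per_variant_criteria": {
            cv.variant_id: {
                "gene": cv.gene,
                "criteria": [c.label for c in cv.criteria],
                "points": cv.points,
                "classification": cv.classification,
            } for cv in classified
        },
        "class_counts": _tier_counts(classified),
        "per_gene_carriers": dict(summary.per_gene_carriers),
    }
    return PipelineResult(classified=classified, decisions=decisions,
                          cascade=cascade, summary=summary, burden=burden,
                          pms2_dropped=dropped, unclassifiable=unclassifiable,
                          audit=audit)


def _tier_counts(classified: Sequence[ClassifiedVariant]) -> dict:
    counts = {"pathogenic": 0, "likely_pathogenic": 0, "vus": 0,
              "likely_benign": 0, "benign": 0}
    for cv in classified:
        counts[cv.classification] += 1
    return counts
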