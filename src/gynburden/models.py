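"""Domain types shared across the pipeline stages.

The pipeline passes variants around as :class:`AnnotatedVariant` records —
one row per distinct variant with every annotation field the prefilter and
the ACMG engine consume. Downstream stages wrap these in decision records
(:class:`FilterDecision`), evidence assignments (:class:`CriterionAssignment`),
classification results (:class:`ClassifiedVariant`) and cohort-level
aggregates (:class:`CohortSummary`, :class:`BurdenRow`).

Controlled vocabularies are plain frozensets of strings so that records
round-trip through TSV without an enum serialisation layer; constructors
validate membership and numeric ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

#: Consequence vocabulary. "other" is anything the effect filter should drop
#: unless splice scores rescue it; UTR SNVs fall under "noncoding".
CONSEQUENCES = frozenset({
    "inframe_indel", "frameshift", "missense", "canonical_splice",
    "start_lost", "stop_lost", "stop_gained", "utr_deletion",
    "synonymous", "noncoding", "other",
})

#: Consequences with moderate or high predicted impact on the protein.
MODERATE_HIGH_IMPACT = frozenset({
    "inframe_indel", "frameshift", "missense", "canonical_splice",
    "start_lost", "stop_lost", "stop_gained", "utr_deletion",
})

#: Null (loss-of-function) consequences eligible for PVS1.
NULL_CONSEQUENCES = frozenset({
    "frameshift", "stop_gained", "canonical_splice", "start_lost",
})

CLINVAR_STATUSES = frozenset({
    "pathogenic_multiple_unanimous", "pathogenic", "likely_pathogenic",
    "vus", "conflicting_blb_vus", "likely_benign", "benign", "absent",
})

IN_SILICO_CONSENSUS = frozenset({"pathogenic", "benign", "mixed"})
LIT_FUNCTIONAL = frozenset({"damaging", "benign_effect", "none"})
LIT_SEGREGATION = frozenset({"cosegregates", "does_not_segregate", "none"})

FIVE_TIER = ("pathogenic", "likely_pathogenic", "vus", "likely_benign", "benign")

CRITERIA = frozenset({
    "PVS1", "PS1", "PS3", "PS4", "PM1", "PM2", "PM4", "PM5",
    "PP1", "PP2", "PP3", "BA1", "BS1", "BS3", "BS4", "BP3", "BP4", "BP7",
})

#: Benign-side criteria; everything else in CRITERIA is pathogenic-side.
BENIGN_CRITERIA = frozenset({"BA1", "BS1", "BS3", "BS4", "BP3", "BP4", "BP7"})

STRENGTHS = frozenset({"very_strong", "strong", "moderate", "supporting", "stand_alone"})


def _check_unit(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {value!r}")


def _check_nonneg(name: str, value: int) -> None:
    if value < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")


@dataclass
class AnnotatedVariant:
    """One distinct variant with all annotations the pipeline consumes.

    ``variant_id`` is ``chrom:pos:ref:alt`` with 1-based coordinates.
    Optional fields default to the documented "no information" value:
    splice scores absent (treated as 0 by filters), no literature evidence,
    mixed in-silico consensus.
    """

    variant_id: str
    gene: str
    transcript: str
    consequence: str
    gnomad_het_count: int
    gnomad_hom_count: int
    gnomad_af: float
    local_carrier_count: int
    local_hom_count: int
    clinvar_status: str
    clinvar_same_aa_pathogenic: bool
    clinvar_other_aa_change_pathogenic: bool
    pext: float
    in_functional_domain: bool
    in_repeat_region: bool
    phastcons: float
    hsf_splice_impact: bool
    nmd_predicted_by_position: bool
    known_pathogenic_downstream: bool
    pms2_unique_region: bool
    lit_patient_count: int = 0
    lit_functional: str = "none"
    lit_segregation: str = "none"
    in_silico_consensus: str = "mixed"
    splice_ada: Optional[float] = None
    splice_rf: Optional[float] = None
    gene_z_score: Optional[float] = None
    splice_frame_disrupted: Optional[bool] = None
    lit_case_control_or: Optional[float] = None
    carrier_ids: tuple[str, ...] = ()
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(
                f"unknown consequence token {self.consequence!r} for {self.variant_id}"
            )
        if self.clinvar_status not in CLINVAR_STATUSES:
            raise ValueError(
                f"unknown clinvar_status {self.clinvar_status!r} for {self.variant_id}"
            )
        if self.in_silico_consensus not in IN_SILICO_CONSENSUS:
            raise ValueError(
                f"unknown in_silico_consensus {self.in_silico_consensus!r}"
            )
        if self.lit_functional not in LIT_FUNCTIONAL:
            raise ValueError(f"unknown lit_functional {self.lit_functional!r}")
        if self.lit_segregation not in LIT_SEGREGATION:
            raise ValueError(f"unknown lit_segregation {self.lit_segregation!r}")
        for name in ("gnomad_het_count", "gnomad_hom_count", "local_carrier_count",
                     "local_hom_count", "lit_patient_count"):
            _check_nonneg(name, getattr(self, name))
        for name in ("gnomad_af", "pext", "phastcons", "splice_ada", "splice_rf"):
            _check_unit(name, getattr(self, name))

    @property
    def max_splice_score(self) -> float:
        """max(ada, rf) with absent scores treated as 0 (no splice rescue)."""
        return max(self.splice_ada or 0.0, self.splice_rf or 0.0)


@dataclass(frozen=True)
class FilterDecision:
    """Outcome of the prefilter for one variant.

    ``stage`` is the stage that excluded the variant, or ``retained`` /
    ``bypass`` for kept variants (``bypass`` marks known-pathogenic variants
    that failed at least one filter but were kept anyway).
    """

    variant_id: str
    retained: bool
    stage: str
    reason: str

    _STAGES = frozenset({"effect", "frequency", "clinvar", "retained", "bypass"})

    def __post_init__(self) -> None:
        if self.stage not in self._STAGES:
            raise ValueError(f"unknown filter stage {self.stage!r}")
        if self.retained != (self.stage in ("retained", "bypass")):
            raise ValueError("retained flag inconsistent with stage")


@dataclass(frozen=True)
class CriterionAssignment:
    """One ACMG criterion applied at a strength level, with a rationale."""

    criterion: str
    strength: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.strength not in STRENGTHS:
            raise ValueError(f"unknown strength {self.strength!r}")
        if self.criterion == "BA1" and self.strength != "stand_alone":
            raise ValueError("BA1 may only be applied stand-alone")
        if self.criterion != "BA1" and self.strength == "stand_alone":
            raise ValueError("only BA1 may be applied stand-alone")
        if self.criterion == "PM2" and self.strength != "supporting":
            raise ValueError("PM2 is applied at supporting strength only (PM2_SUP)")

    @property
    def label(self) -> str:
        return f"{self.criterion}@{self.strength}"


@dataclass(frozen=True)
class GeneProfile:
    """Gene-level configuration the engine consults for every variant."""

    gene: str
    transcript: str
    chrom: str
    phenotype: str
    haploinsufficient: bool
    z_score: float
    bs1_cutoff: float
    homology_masked: bool


@dataclass
class ClassifiedVariant:
    """A variant with its evidence set, point total, class and audit trail."""

    variant_id: str
    gene: str
    criteria: tuple[CriterionAssignment, ...]
    points: int
    classification: str
    audit: tuple[dict, ...] = ()

    def __post_init__(self) -> None:
        if self.classification not in FIVE_TIER:
            raise ValueError(f"unknown classification {self.classification!r}")

    @property
    def is_plp(self) -> bool:
        return self.classification in ("pathogenic", "likely_pathogenic")


@dataclass
class CohortSummary:
    """Per-gene unique-heterozygote carrier counts for a cohort of size N."""

    n_individuals: int
    per_gene_carriers: Mapping[str, int]
    per_gene_variants: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        for gene, count in self.per_gene_carriers.items():
            if not (0 <= count <= self.n_individuals):
                raise ValueError(f"carrier count for {gene} outside [0, N]")

    @property
    def total_carriers(self) -> int:
        """Sum over genes; an individual with carriage in two genes counts twice."""
        return sum(self.per_gene_carriers.values())


@dataclass
class ControlSummary:
    """Control-population carrier summary: counts or frequencies per gene."""

    n_individuals: int
    per_gene_count: Mapping[str, Optional[int]]
    per_gene_freq_percent: Mapping[str, Optional[float]]


@dataclass
class BurdenRow:
    """One gene's 2x2 comparison against the control population.

    Frequencies and ORs are stored rounded to the table's display convention
    (half-up; 2 decimals for percentages and ORs, 3 for the chi-square
    statistic); ``None`` marks NA cells (zero study carriers or a zero cell).
    """

    gene: str
    study_count: Optional[int]
    study_freq: Optional[float]
    control_count: Optional[int]
    control_freq: Optional[float]
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    chi2: Optional[float]
    p_value: Optional[float]


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for a generated variant."""

    variant_id: str
    gene: str
    intended_class: str

    def __post_init__(self) -> None:
        if self.intended_class not in FIVE_TIER:
            raise ValueError(f"unknown intended_class {self.intended_class!r}")
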