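"""Synthetic annotated cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a panel-gene cohort of N individuals in which each individual
carries a pathogenic or likely pathogenic variant in gene *g* independently
with probability ``per_gene_prevalence[g]``, a catalogue of distinct
variants whose annotation bundles are drawn from per-truth-class regimes,
and a control population summarized as per-gene carrier counts.

Each truth class maps to an annotation regime constructed so the prefilter
and classification engine treat it as intended:

* pathogenic      — NMD-predicted null in a haploinsufficient gene, absent
                    from gnomAD, damaging functional studies (PVS1 + PM2 +
                    PS3, some with PS4: >= 13 points);
* likely_pathogenic — null or frame-disrupting canonical-splice variant,
                    absent from gnomAD, no literature (PVS1 + PM2 = 9);
* vus             — rare missense or splice-suspicious synonymous variant
                    with no further evidence (PM2 only);
* likely_benign   — ClinVar likely benign and/or too frequent, removed by
                    the prefilter;
* benign          — ClinVar benign / B-LB-vs-VUS conflict at high
                    frequency, removed by the prefilter.

Unconstrained annotation fields are filled from documented defaults (e.g.
pext ~ Uniform(0.6, 1) for coding variants) so downstream code never sees
missing fields unless missingness itself is being exercised. Identical
config and seed give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .burden import control_count_from_freq, prevalence_percent
from .models import AnnotatedVariant, ControlSummary, FIVE_TIER, TruthRecord
from .panel import PanelConfig, default_panel, reference_summary

#: Class-mix proportions mirroring the published cascade (694 candidate
#: variants: 60 pathogenic, 14 likely pathogenic, 417 VUS, the rest
#: benign-leaning records removed during filtering or classified B/LB).
DEFAULT_CLASS_MIX = {
    "pathogenic": 0.087,
    "likely_pathogenic": 0.020,
    "vus": 0.601,
    "likely_benign": 0.248,
    "benign": 0.044,
}


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters; defaults reproduce the study design."""

    cohort_size: int
    control_size: int
    per_gene_prevalence: Mapping[str, float]
    control_prevalence: Mapping[str, float]
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    n_distinct_variants: int = 694
    seed: int = 0

    def validate(self, panel: PanelConfig) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        if self.control_size <= 0:
            raise ValueError("control_size must be positive")
        if self.n_distinct_variants < 0:
            raise ValueError("n_distinct_variants must be non-negative")
        for name, mapping in (("per_gene_prevalence", self.per_gene_prevalence),
                              ("control_prevalence", self.control_prevalence)):
            for gene, p in mapping.items():
                if gene not in panel.profiles:
                    raise ValueError(f"{name} names unknown gene {gene!r}")
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{gene}] = {p!r} outside [0, 1]")
        for cls, prop in self.class_mix.items():
            if cls not in FIVE_TIER:
                raise ValueError(f"class_mix names unknown class {cls!r}")
            if prop < 0:
                raise ValueError("class_mix proportions must be non-negative")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")


def default_config(seed: int = 0, panel: Optional[PanelConfig] = None) -> SimulationConfig:
    """The study conditions: 7,091-exome cohort, 134,187 controls, per-gene
    prevalences equal to the published study and control carrier frequencies."""
    panel = panel or default_panel()
    ref = reference_summary()
    prev = {g: ref["genes"][g]["carriers"] / ref["n_study"] for g in panel.genes}
    ctrl = {g: (ref["genes"][g]["control_freq_percent"] or 0.0) / 100.0
            for g in panel.genes}
    return SimulationConfig(
        cohort_size=ref["n_study"],
        control_size=ref["n_control"],
        per_gene_prevalence=prev,
        control_prevalence=ctrl,
        seed=seed,
    )


@dataclass
class CohortTables:
    """Everything one simulated cohort comprises."""

    variants: list[AnnotatedVariant]
    genotypes: dict[str, tuple[str, ...]]
    truth: list[TruthRecord]


def _class_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment: exact proportions, deterministic."""
    classes = [c for c in FIVE_TIER if mix.get(c, 0) > 0]
    raw = {c: n * mix[c] for c in classes}
    counts = {c: int(raw[c]) for c in classes}
    short = n - sum(counts.values())
    for c in sorted(classes, key=lambda c: (raw[c] - int(raw[c]), c), reverse=True)[:short]:
        counts[c] += 1
    return counts


_BASES = ("A", "C", "G", "T")


def _common(vid, gene, profile, rng) -> dict:
    """Fields shared by every regime; neutral defaults."""
    return dict(
        variant_id=vid, gene=gene, transcript=profile.transcript,
        gnomad_het_count=0, gnomad_hom_count=0, gnomad_af=0.0,
        local_carrier_count=0, local_hom_count=0,
        clinvar_same_aa_pathogenic=False, clinvar_other_aa_change_pathogenic=False,
        pext=float(rng.uniform(0.6, 1.0)),
        gene_z_score=profile.z_score,
        in_functional_domain=False, in_repeat_region=False,
        phastcons=float(rng.uniform(0.7, 1.0)),
        hsf_splice_impact=False,
        nmd_predicted_by_position=False, known_pathogenic_downstream=False,
        pms2_unique_region=True,
        lit_patient_count=0, lit_functional="none", lit_segregation="none",
        in_silico_consensus="mixed",
    )


def _make_variant(idx: int, truth_class: str, gene: str, panel: PanelConfig,
                  rng: np.random.Generator) -> AnnotatedVariant:
    profile = panel.profile(gene)
    pos = 100_000 + 37 * idx
    ref, alt = _BASES[idx % 4], _BASES[(idx + 1) % 4]
    if truth_class == "pathogenic":
        vid = f"{profile.chrom}:{pos}:{ref}{alt}:{ref}" if idx % 2 else f"{profile.chrom}:{pos}:{ref}:{alt}"
        f = _common(vid, gene, profile, rng)
        f.update(
            consequence="frameshift" if idx % 2 else "stop_gained",
            nmd_predicted_by_position=True,
            known_pathogenic_downstream=bool(rng.integers(0, 2)),
            clinvar_status="pathogenic_multiple_unanimous" if idx % 2 else "pathogenic",
            lit_functional="damaging",
            lit_patient_count=6 if idx % 3 == 0 else 0,
            in_silico_consensus="pathogenic",
        )
        if idx % 7 == 3:
            # founder-like: known pathogenic yet frequent in controls, so it
            # fails the frequency filter and is kept via the bypass
            af = float(rng.uniform(5e-4, 2e-3))
            f.update(clinvar_status="pathogenic_multiple_unanimous",
                     gnomad_af=af,
                     gnomad_het_count=int(round(af * 2 * 134_187)),
                     lit_case_control_or=float(rng.uniform(6.0, 12.0)))
    elif truth_class == "likely_pathogenic":
        f = _common(f"{profile.chrom}:{pos}:{ref}:{alt}", gene, profile, rng)
        if idx % 2:
            f.update(consequence="canonical_splice",
                     splice_ada=float(rng.uniform(0.9, 1.0)),
                     splice_rf=float(rng.uniform(0.9, 1.0)),
                     splice_frame_disrupted=True)
        else:
            f.update(consequence="frameshift", nmd_predicted_by_position=True)
        f.update(clinvar_status="likely_pathogenic" if idx % 3 == 0 else "absent")
    elif truth_class == "vus":
        f = _common(f"{profile.chrom}:{pos}:{ref}:{alt}", gene, profile, rng)
        af = float(rng.uniform(0.0, 1.5e-5))
        if idx % 5 == 0:
            f.update(consequence="synonymous",
                     splice_ada=float(rng.uniform(0.6, 0.9)),
                     hsf_splice_impact=True)
        else:
            f.update(consequence="missense")
        f.update(gnomad_af=af,
                 gnomad_het_count=int(round(af * 2 * 134_187)),
                 clinvar_status="vus" if idx % 2 else "absent",
                 local_carrier_count=int(rng.integers(1, 6)))
    elif truth_class == "likely_benign":
        f = _common(f"{profile.chrom}:{pos}:{ref}:{alt}", gene, profile, rng)
        if idx % 2:
            af = float(rng.uniform(2e-4, 8e-4))  # too many gnomAD hets: frequency stage
            f.update(consequence="missense", gnomad_af=af,
                     gnomad_het_count=int(round(af * 2 * 134_187)),
                     clinvar_status="likely_benign")
        else:
            f.update(consequence="missense", gnomad_af=1e-5, gnomad_het_count=3,
                     clinvar_status="likely_benign")  # ClinVar stage
        f.update(local_carrier_count=int(rng.integers(1, 9)))
    elif truth_class == "benign":
        f = _common(f"{profile.chrom}:{pos}:{ref}:{alt}", gene, profile, rng)
        if idx % 2:
            af = float(rng.uniform(0.05, 0.2))
            f.update(consequence="missense", gnomad_af=af,
                     gnomad_het_count=int(round(af * 2 * 134_187 * 0.8)),
                     gnomad_hom_count=int(round(af * af * 134_187)),
                     clinvar_status="benign",
                     local_carrier_count=int(rng.integers(30, 200)))
        else:
            f.update(consequence="missense", gnomad_af=5e-6, gnomad_het_count=1,
                     clinvar_status="conflicting_blb_vus",
                     local_carrier_count=int(rng.integers(1, 9)))
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(truth_class)
    return AnnotatedVariant(**f)


def generate_cohort(config: SimulationConfig,
                    panel: Optional[PanelConfig] = None) -> CohortTables:
    """Draw the variant catalogue, per-individual carriage, and truth labels.

    P/LP-truth variants are allocated round-robin across the genes with
    non-zero prevalence (every such gene is guaranteed at least one, so each
    sampled carrier can be assigned a concrete variant); other classes cycle
    over the whole panel. Carriage is an independent Bernoulli draw per
    individual per gene, and an individual carries at most one variant per
    gene.
    """
    panel = panel or default_panel()
    config.validate(panel)
    rng = np.random.default_rng(config.seed)

    counts = _class_counts(config.n_distinct_variants, config.class_mix)
    genes_pos = [g for g in panel.genes if config.per_gene_prevalence.get(g, 0) > 0]
    n_plp = counts.get("pathogenic", 0) + counts.get("likely_pathogenic", 0)
    if genes_pos and n_plp < len(genes_pos):
        raise ValueError(
            f"{len(genes_pos)} genes have non-zero prevalence but only {n_plp} "
            "P/LP-truth variants are being generated; raise n_distinct_variants "
            "or the P/LP class-mix proportions")

    variants: list[AnnotatedVariant] = []
    truth: list[TruthRecord] = []
    plp_by_gene: dict[str, list[str]] = {g: [] for g in genes_pos}
    idx = 0
    plp_i = 0
    for cls in FIVE_TIER:
        for k in range(counts.get(cls, 0)):
            if cls in ("pathogenic", "likely_pathogenic") and genes_pos:
                gene = genes_pos[plp_i % len(genes_pos)]
                plp_i += 1
            else:
                gene = panel.genes[idx % len(panel.genes)]
            v = _make_variant(idx, cls, gene, panel, rng)
            variants.append(v)
            truth.append(TruthRecord(v.variant_id, gene, cls))
            if cls in ("pathogenic", "likely_pathogenic") and genes_pos:
                plp_by_gene[gene].append(v.variant_id)
            idx += 1

    # carriage: Bernoulli per individual per gene, then assign each carrier
    # to one of the gene's P/LP variants uniformly
    individuals = np.array([f"I{i:05d}" for i in range(config.cohort_size)])
    genotypes: dict[str, list[str]] = {v.variant_id: [] for v in variants}
    used_per_gene: dict[str, set] = {g: set() for g in panel.genes}
    for gene in genes_pos:
        p = config.per_gene_prevalence[gene]
        mask = rng.random(config.cohort_size) < p
        carriers = individuals[mask]
        vids = plp_by_gene[gene]
        choices = rng.integers(0, len(vids), size=carriers.size)
        for person, which in zip(carriers, choices):
            genotypes[vids[which]].append(str(person))
        used_per_gene[gene].update(str(p_) for p_ in carriers)

    # background carriage for non-P/LP variants, avoiding a second same-gene
    # variant in any individual; genes with zero prevalence carry nothing
    for v in variants:
        want = v.local_carrier_count
        if want <= 0 or genotypes[v.variant_id]:
            continue
        if config.per_gene_prevalence.get(v.gene, 0) == 0:
            continue
        picks = rng.choice(config.cohort_size, size=min(want * 3, config.cohort_size),
                           replace=False)
        chosen = []
        for i in picks:
            person = str(individuals[i])
            if person in used_per_gene[v.gene]:
                continue
            chosen.append(person)
            if len(chosen) == want:
                break
        genotypes[v.variant_id] = chosen
        used_per_gene[v.gene].update(chosen)

    final: list[AnnotatedVariant] = []
    for v in variants:
        ids = tuple(sorted(genotypes[v.variant_id]))
        v.carrier_ids = ids
        v.local_carrier_count = len(ids)
        final.append(v)
    return CohortTables(variants=final,
                        genotypes={k: tuple(sorted(ids)) for k, ids in genotypes.items()},
                        truth=truth)


def generate_control(config: SimulationConfig,
                     panel: Optional[PanelConfig] = None,
                     mode: str = "sampled") -> ControlSummary:
    """Per-gene control carrier counts.

    ``sampled`` draws counts Binomial(control_size, control_prevalence[g]);
    ``fixed`` emits exactly the configured frequencies without sampling
    (counts reconstructed by half-up rounding), for reproducing printed
    control columns.
    """
    panel = panel or default_panel()
    config.validate(panel)
    if mode not in ("sampled", "fixed"):
        raise ValueError(f"unknown control mode {mode!r}")
    counts: dict[str, Optional[int]] = {}
    freqs: dict[str, Optional[float]] = {}
    if mode == "fixed":
        for g in panel.genes:
            f = 100.0 * config.control_prevalence.get(g, 0.0)
            freqs[g] = f
            counts[g] = control_count_from_freq(f, config.control_size)
    else:
        rng = np.random.default_rng([config.seed, 1])
        for g in panel.genes:
            c = int(rng.binomial(config.control_size, config.control_prevalence.get(g, 0.0)))
            counts[g] = c
            freqs[g] = prevalence_percent(c, config.control_size)
    return ControlSummary(n_individuals=config.control_size,
                          per_gene_count=counts, per_gene_freq_percent=freqs)
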