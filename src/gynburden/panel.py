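"""Gene panel and threshold configuration.

The shipped default configuration carries the 17-gene panel (symbol,
transcript, phenotype) together with the per-gene classification profile
(haploinsufficiency, missense-constraint z, BS1 frequency cutoff, PMS2
homology masking) and every numeric cutoff used anywhere in the pipeline.
All cutoffs are overridable from a user YAML file; the audit JSON echoes
the effective values.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace, asdict
from typing import Mapping

import yaml

from .models import GeneProfile


@dataclass(frozen=True)
class Thresholds:
    """Every tunable cutoff, with the shipped defaults.

    Comparisons are strict or inclusive exactly as the field comments in the
    shipped YAML state; predicates in :mod:`gynburden.prefilter` and
    :mod:`gynburden.acmg` implement them.
    """

    splice_score_min: float = 0.5
    gnomad_het_max: int = 10
    local_carrier_max: int = 20
    gnomad_hom_max: int = 3
    local_hom_max: int = 3
    pext_min: float = 0.5
    pp2_z_min: float = 3.09
    ba1_af: float = 0.05
    pm2_af_max: float = 2e-5
    ps4_common_af: float = 1e-5
    ps4_or_min: float = 5.0
    ps4_patients_strong: int = 4
    ps4_patients_moderate: int = 2
    ps4_patients_supporting: int = 1
    bp7_phastcons_max: float = 0.2
    yates_correction: bool = False


@dataclass
class PanelConfig:
    """The 17-gene panel plus thresholds; the single source of cutoffs."""

    profiles: Mapping[str, GeneProfile]
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.profiles)

    def profile(self, gene: str) -> GeneProfile:
        try:
            return self.profiles[gene]
        except KeyError:
            raise KeyError(
                f"gene {gene!r} is not in the {len(self.profiles)}-gene panel"
            ) from None

    def effective_thresholds(self) -> dict:
        """All effective cutoff values, for the audit record."""
        return asdict(self.thresholds)


def _parse(doc: dict) -> PanelConfig:
    profiles = {}
    for rec in doc["genes"]:
        profiles[rec["symbol"]] = GeneProfile(
            gene=rec["symbol"],
            transcript=rec["transcript"],
            chrom=str(rec.get("chrom", ".")),
            phenotype=rec.get("phenotype", ""),
            haploinsufficient=bool(rec["haploinsufficient"]),
            z_score=float(rec["z_score"]),
            bs1_cutoff=float(rec["bs1_cutoff"]),
            homology_masked=bool(rec.get("homology_masked", False)),
        )
    thresholds = Thresholds(**doc.get("thresholds", {}))
    return PanelConfig(profiles=profiles, thresholds=thresholds)


def default_panel() -> PanelConfig:
    """Load the shipped 17-gene panel and default thresholds."""
    ref = importlib.resources.files("gynburden.data") / "panel.yaml"
    return _parse(yaml.safe_load(ref.read_text()))


def load_panel(path: str) -> PanelConfig:
    """Load a panel/threshold configuration from a YAML file."""
    with open(path) as fh:
        return _parse(yaml.safe_load(fh))


def with_thresholds(panel: PanelConfig, **overrides) -> PanelConfig:
    """Return a copy of ``panel`` with selected thresholds replaced."""
    return PanelConfig(
        profiles=dict(panel.profiles),
        thresholds=replace(panel.thresholds, **overrides),
    )


def reference_summary() -> dict:
    """The published per-gene carrier counts and control frequencies.

    Printed summary numbers from the population survey this pipeline
    re-implements: study N, control N, per-gene distinct P/LP variants,
    heterozygote carrier counts, and control carrier frequencies (percent).
    Used by the analysis drivers to reconstruct the published burden table.
    """
    ref = importlib.resources.files("gynburden.data") / "reference_cohort.yaml"
    return yaml.safe_load(ref.read_text())
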