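import hypothesis
import pytest

from gynburden.models import AnnotatedVariant
from gynburden.panel import PanelConfig, Thresholds, default_panel

hypothesis.settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=150)
hypothesis.settings.load_profile("default")


@pytest.fixture(scope="session")
def panel() -> PanelConfig:
    return default_panel()


@pytest.fixture(scope="session")
def thresholds(panel) -> Thresholds:
    return panel.thresholds


def make_variant(**overrides) -> AnnotatedVariant:
    """A missense variant that passes every prefilter stage; override at will."""
    fields = dict(
        variant_id="17:100000:G:A",
        gene="BRCA1",
        transcript="NM_007294.4",
        consequence="missense",
        gnomad_het_count=0,
        gnomad_hom_count=0,
        gnomad_af=0.0,
        local_carrier_count=1,
        local_hom_count=0,
        clinvar_status="absent",
        clinvar_same_aa_pathogenic=False,
        clinvar_other_aa_change_pathogenic=False,
        pext=0.9,
        in_functional_domain=False,
        in_repeat_region=False,
        phastcons=0.9,
        hsf_splice_impact=False,
        nmd_predicted_by_position=False,
        known_pathogenic_downstream=False,
        pms2_unique_region=True,
    )
    fields.update(overrides)
    return AnnotatedVariant(**fields)
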