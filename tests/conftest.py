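from __future__ import annotations

from functools import lru_cache

import pytest

from variantcompare.annotation import annotate, rarity_size
from variantcompare.comparison import compare
from variantcompare.models import (
    AnnotatedVariant,
    EffectKB,
    EffectRecord,
    PersonReport,
    Zygosity,
)
from variantcompare.synthetic_data import SimulationConfig, generate_kb, simulate_family


def make_effect(**overrides) -> EffectRecord:
    fields = dict(
        variant_name="GENE0-X0Y",
        rsid="rs1000",
        risk_allele="A",
        base_impact="pathogenic",
        inheritance="recessive",
        certainty="well_established",
        allele_frequency=0.01,
        category="Metabolism",
        clinical_importance="test entry",
        effect_summary="a synthetic effect",
    )
    fields.update(overrides)
    return EffectRecord(**fields)


def make_annotated(effect=None, zygosity="heterozygous", **effect_overrides):
    from variantcompare.annotation import derive_display_impact

    if effect is None:
        effect = make_effect(**effect_overrides)
    zyg = Zygosity(zygosity)
    return AnnotatedVariant(
        effect=effect,
        zygosity=zyg,
        display_impact=derive_display_impact(
            effect.base_impact, effect.inheritance, zyg
        ),
        rarity_size=rarity_size(effect.allele_frequency),
    )


@lru_cache(maxsize=None)
def make_family(seed: int, n_variants: int = 30, n_children: int = 2):
    """Simulated family pipeline output, cached per condition (immutable)."""
    cfg = SimulationConfig(n_variants=n_variants, n_children=n_children, seed=seed)
    kb = generate_kb(cfg)
    members = simulate_family(kb, cfg)
    reports = tuple(annotate(g, kb) for g in members.values())
    return kb, members, reports


def random_comparison(seed: int, n_persons: int, n_variants: int = 25):
    _, _, reports = make_family(seed, n_variants=n_variants)
    return compare(reports[:n_persons])


@pytest.fixture
def tiny_kb() -> EffectKB:
    """Handcrafted 6-entry knowledge base covering every impact class,
    both inheritance modes relevant to carrier status, and all certainty
    levels. Variant names follow the GENE-change convention."""
    return EffectKB(
        records=(
            make_effect(
                variant_name="FUT2-W154X", rsid="rs601338", risk_allele="A",
                base_impact="pathogenic", inheritance="recessive",
                certainty="well_established", allele_frequency=0.4,
                category="Immune System",
                clinical_importance="norovirus resistance, recessive",
                effect_summary="Nonsecretor allele; homozygotes resist some infections.",
            ),
            make_effect(
                variant_name="ADA-D8N", rsid="rs73598374", risk_allele="T",
                base_impact="pathogenic", inheritance="dominant",
                certainty="likely", allele_frequency=0.05,
                category="Metabolism",
                clinical_importance="altered enzyme activity",
                effect_summary="Associated with adenosine deaminase changes.",
            ),
            make_effect(
                variant_name="DPYD-M166V", rsid="rs2297595", risk_allele="C",
                base_impact="pharmacogenetic", inheritance="unknown",
                certainty="uncertain", allele_frequency=0.1,
                category="Drug Response",
                clinical_importance="fluoropyrimidine toxicity risk",
                effect_summary="May alter drug metabolism.",
            ),
            make_effect(
                variant_name="APOC3-R19X", rsid="rs76353203", risk_allele="T",
                base_impact="protective", inheritance="unknown",
                certainty="likely", allele_frequency=0.002,
                category="Cardiovascular",
                clinical_importance="lower triglycerides",
                effect_summary="Loss of function, protective lipid profile.",
            ),
            make_effect(
                variant_name="MTHFR-A222V", rsid="rs1801133", risk_allele="A",
                base_impact="benign", inheritance="unknown",
                certainty="well_established", allele_frequency=0.3,
                category="Metabolism",
                clinical_importance="common polymorphism",
                effect_summary="Mildly reduced enzyme activity, benign.",
            ),
            make_effect(
                variant_name="BRCA2-K3326X", rsid="rs11571833", risk_allele="T",
                base_impact="pathogenic", inheritance="recessive",
                certainty="uncertain", allele_frequency=0.008,
                category="Cancer",
                clinical_importance="modest cancer association",
                effect_summary="Truncating allele with Alzheimer-unrelated effects.",
            ),
        ),
        source_label="handcrafted-synthetic",
    )


@pytest.fixture
def family_reports() -> tuple[PersonReport, ...]:
    _, _, reports = make_family(7, n_variants=40)
    return reports
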