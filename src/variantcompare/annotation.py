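"""Annotate one person's genotypes against the variant-effect knowledge base.

The pipeline step is :func:`annotate`: join genotype calls to knowledge-base
entries on rsid, keep entries whose risk allele is actually carried, and
classify each match by

* **zygosity** -- how many of the person's alleles equal the risk allele
  (one of two: heterozygous; two of two: homozygous; the single allele of a
  length-1 call on X/Y/MT: hemizygous);
* **display impact** -- the published effect class, except that a
  heterozygous genotype at a *recessive pathogenic* variant is displayed as
  *carrier*: such a person is not expected to be affected themselves but
  can transmit the allele to offspring;
* **rarity size** -- a glyph-size score in (0, 1] that grows as the allele
  gets rarer (downstream views draw rare variants large).
"""

from __future__ import annotations

import math

from .errors import ValidationError
from .models import (
    AnnotatedVariant,
    BaseImpact,
    DisplayImpact,
    EffectKB,
    GenotypeRecord,
    GenotypeSet,
    Inheritance,
    PersonReport,
    Zygosity,
)

__all__ = [
    "call_zygosity",
    "derive_display_impact",
    "rarity_size",
    "annotate",
    "DEFAULT_F_MIN",
    "DEFAULT_S_MIN",
]

#: Frequency floor: alleles rarer than this are drawn at full size.
DEFAULT_F_MIN = 1e-4
#: Size of the commonest possible allele (frequency 1); keeps every glyph
#: visible.
DEFAULT_S_MIN = 0.05


def call_zygosity(record: GenotypeRecord, risk_allele: str) -> Zygosity | None:
    """Zygosity of ``risk_allele`` in one genotype call, or None if absent.

    Returns None for no-calls (any ``-`` allele) and for genotypes that do
    not contain the risk allele. A length-1 genotype containing the risk
    allele is hemizygous (single-copy chromosomes).
    """
    if record.is_no_call:
        return None
    count = record.genotype.count(risk_allele)
    if count == 0:
        return None
    if len(record.genotype) == 1:
        return Zygosity.HEMIZYGOUS
    return Zygosity.HETEROZYGOUS if count == 1 else Zygosity.HOMOZYGOUS


def derive_display_impact(
    base_impact: BaseImpact,
    inheritance: Inheritance,
    zygosity: Zygosity,
) -> DisplayImpact:
    """Displayed effect class for one person.

    Carrier iff the variant is pathogenic, recessive, and heterozygous.
    Homozygous or hemizygous recessive stays pathogenic (both/all copies are
    affected), dominant is pathogenic at any zygosity, and unknown
    inheritance is treated conservatively like dominant (never carrier).
    Non-pathogenic base impacts pass through unchanged.
    """
    base_impact = BaseImpact(base_impact)
    if (
        base_impact is BaseImpact.PATHOGENIC
        and Inheritance(inheritance) is Inheritance.RECESSIVE
        and Zygosity(zygosity) is Zygosity.HETEROZYGOUS
    ):
        return DisplayImpact.CARRIER
    return DisplayImpact(base_impact.value)


def rarity_size(
    allele_frequency: float,
    f_min: float = DEFAULT_F_MIN,
    s_min: float = DEFAULT_S_MIN,
) -> float:
    """Glyph-size score in (0, 1], strictly decreasing in allele frequency.

    The score is affine in log10 frequency: frequencies at or below the
    floor ``f_min`` map to 1.0, frequency 1 maps to ``s_min``, and the
    mapping is strictly monotone in between, so glyph ordering always
    matches rarity ordering::

        size(f) = s_min + (1 - s_min) * log10(1/f) / log10(1/f_min),
        f clamped to [f_min, 1]

    Raises for frequencies outside (0, 1].
    """
    if not 0.0 < allele_frequency <= 1.0:
        raise ValidationError(
            f"allele_frequency {allele_frequency} outside (0, 1]"
        )
    if not 0.0 < f_min < 1.0:
        raise ValidationError(f"f_min {f_min} outside (0, 1)")
    if not 0.0 < s_min < 1.0:
        raise ValidationError(f"s_min {s_min} outside (0, 1)")
    f = max(allele_frequency, f_min)
    return s_min + (1.0 - s_min) * math.log10(1.0 / f) / math.log10(1.0 / f_min)


def annotate(
    genotypes: GenotypeSet,
    kb: EffectKB,
    f_min: float = DEFAULT_F_MIN,
    s_min: float = DEFAULT_S_MIN,
) -> PersonReport:
    """Join one person's genotypes against the knowledge base.

    The report contains exactly the knowledge-base entries whose risk allele
    appears at least once in the person's calls; only variants with known
    effects are reported, and genotypes at rsids absent from the knowledge
    base are silently ignored. Output order is deterministic: by health
    category, then variant name -- independent of genotype file order.
    """
    matched: list[AnnotatedVariant] = []
    for effect in kb:
        record = genotypes.get(effect.rsid)
        if record is None:
            continue
        zygosity = call_zygosity(record, effect.risk_allele)
        if zygosity is None:
            continue
        matched.append(
            AnnotatedVariant(
                effect=effect,
                zygosity=zygosity,
                display_impact=derive_display_impact(
                    effect.base_impact, effect.inheritance, zygosity
                ),
                rarity_size=rarity_size(effect.allele_frequency, f_min, s_min),
            )
        )
    matched.sort(key=lambda v: (v.effect.category, v.effect.variant_name))
    return PersonReport(person_id=genotypes.person_id, variants=tuple(matched))
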