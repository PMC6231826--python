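"""Multi-person comparison: partition variants by membership signature.

Given 2-4 annotated person reports, every distinct variant key is assigned
to exactly one *membership class* -- the exact subset of persons who carry
it. The same variant may look different per person (carrier in a
heterozygous parent, pathogenic in a homozygous child); each class entry
therefore keeps every carrying person's annotated view.

Class order is fixed so downstream layouts can place fully shared variants
first without re-sorting: the all-persons signature comes first, then
signatures by descending size, ties broken by person order.
"""

from __future__ import annotations

import json
from typing import IO, Sequence

from .errors import ArityError, FormatError, IdentityError
from .models import (
    AnnotatedVariant,
    ComparisonEntry,
    ComparisonReport,
    DisplayImpact,
    EffectRecord,
    FilterSpec,
    PersonReport,
    VariantKey,
)

__all__ = [
    "compare",
    "shared_count",
    "compare_counts",
    "carrier_outlook",
    "comparison_to_json",
    "comparison_from_json",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def signature_sort_key(persons: Sequence[str]):
    """Class ordering: descending signature size, then person order."""
    index = {p: i for i, p in enumerate(persons)}

    def key(sig: tuple[str, ...]):
        return (-len(sig), tuple(index[p] for p in sig))

    return key


def compare(reports: Sequence[PersonReport]) -> ComparisonReport:
    """Partition the union of 2-4 person reports into membership classes.

    Raises :class:`ArityError` outside 2-4 reports and
    :class:`IdentityError` on duplicate person ids. Within each class,
    entries are ordered by health category then variant name.
    """
    if not 2 <= len(reports) <= 4:
        raise ArityError(f"comparisons take 2-4 reports, got {len(reports)}")
    persons = tuple(r.person_id for r in reports)
    if len(set(persons)) != len(persons):
        raise IdentityError("duplicate person_id among compared reports")

    by_key: dict[VariantKey, dict[str, AnnotatedVariant]] = {}
    for report in reports:
        for variant in report:
            by_key.setdefault(variant.key, {})[report.person_id] = variant

    classes: dict[tuple[str, ...], list[ComparisonEntry]] = {}
    for key, per_person in by_key.items():
        sig = tuple(p for p in persons if p in per_person)
        classes.setdefault(sig, []).append(
            ComparisonEntry(key=key, per_person=per_person)
        )

    ordered: dict[tuple[str, ...], tuple[ComparisonEntry, ...]] = {}
    for sig in sorted(classes, key=signature_sort_key(persons)):
        entries = sorted(
            classes[sig],
            key=lambda e: (e.effect.category, e.effect.variant_name),
        )
        ordered[sig] = tuple(entries)
    return ComparisonReport(persons=persons, classes=ordered)


def shared_count(
    cmp: ComparisonReport,
    persons: Sequence[str],
    filter_spec: FilterSpec | None = None,
) -> int:
    """Number of filtered variants carried by *every* person in ``persons``.

    Sums class sizes over all membership signatures that contain the whole
    subset. Answers queries like "which child shares the most
    cancer-related variants with parent 1?" via an argmax over calls.
    """
    subset = set(persons)
    if len(subset) < 2:
        raise ArityError("shared_count needs at least 2 persons")
    unknown = subset - set(cmp.persons)
    if unknown:
        raise IdentityError(f"unknown person(s) {sorted(unknown)}")
    view = _filtered(cmp, filter_spec)
    return sum(
        len(entries)
        for sig, entries in view.classes.items()
        if subset <= set(sig)
    )


def compare_counts(
    cmp: ComparisonReport,
    person_a: str,
    person_b: str,
    filter_spec: FilterSpec | None = None,
) -> str:
    """Relate two persons' filtered variant counts: 'more'/'fewer'/'same'.

    Antisymmetric under argument swap.
    """
    for p in (person_a, person_b):
        if p not in cmp.persons:
            raise IdentityError(f"unknown person {p!r}")
    view = _filtered(cmp, filter_spec)
    count_a = len(view.keys_for(person_a)) if person_a in view.persons else 0
    count_b = len(view.keys_for(person_b)) if person_b in view.persons else 0
    if count_a > count_b:
        return "more"
    if count_a < count_b:
        return "fewer"
    return "same"


def carrier_outlook(report: PersonReport) -> list[AnnotatedVariant]:
    """Variants this person carries without being affected themselves.

    Exactly the variants displayed as carrier status (heterozygous recessive
    pathogenic): relevant for offspring, not for the person's own health.
    Report order is preserved.
    """
    return [v for v in report if v.display_impact is DisplayImpact.CARRIER]


def _filtered(cmp: ComparisonReport, spec: FilterSpec | None) -> ComparisonReport:
    if spec is None or spec.is_empty:
        return cmp
    from .filtering import apply_filter  # local import: filtering builds on this module

    return apply_filter(cmp, spec)


# ---------------------------------------------------------------------------
# JSON serialization


def _variant_to_json(v: AnnotatedVariant) -> dict:
    e = v.effect
    return {
        "variant_name": e.variant_name,
        "rsid": e.rsid,
        "risk_allele": e.risk_allele,
        "base_impact": e.base_impact.value,
        "inheritance": e.inheritance.value,
        "certainty": e.certainty.value,
        "allele_frequency": e.allele_frequency,
        "category": e.category,
        "clinical_importance": e.clinical_importance,
        "effect_summary": e.effect_summary,
        "zygosity": v.zygosity.value,
        "display_impact": v.display_impact.value,
        "rarity_size": v.rarity_size,
    }


def _variant_from_json(obj: dict) -> AnnotatedVariant:
    effect = EffectRecord(
        variant_name=obj["variant_name"],
        rsid=obj["rsid"],
        risk_allele=obj["risk_allele"],
        base_impact=obj["base_impact"],
        inheritance=obj["inheritance"],
        certainty=obj["certainty"],
        allele_frequency=obj["allele_frequency"],
        category=obj["category"],
        clinical_importance=obj["clinical_importance"],
        effect_summary=obj["effect_summary"],
    )
    return AnnotatedVariant(
        effect=effect,
        zygosity=obj["zygosity"],
        display_impact=obj["display_impact"],
        rarity_size=obj["rarity_size"],
    )


def comparison_to_json(cmp: ComparisonReport, sink: IO[str] | None = None) -> str:
    """Serialize a comparison as versioned JSON (returns the text)."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "persons": list(cmp.persons),
        "classes": [
            {
                "signature": list(sig),
                "variants": [
                    {
                        "key": list(entry.key),
                        "per_person": {
                            p: _variant_to_json(v)
                            for p, v in entry.per_person.items()
                        },
                    }
                    for entry in entries
                ],
            }
            for sig, entries in cmp.classes.items()
        ],
    }
    text = json.dumps(doc, indent=2, sort_keys=False)
    if sink is not None:
        sink.write(text)
    return text


def comparison_from_json(source: str | IO[str]) -> ComparisonReport:
    """Inverse of :func:`comparison_to_json`."""
    text = source if isinstance(source, str) else source.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid comparison JSON: {exc}") from None
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise FormatError(
            f"unsupported schema_version {doc.get('schema_version')!r}"
        )
    try:
        persons = tuple(doc["persons"])
        classes: dict[tuple[str, ...], tuple[ComparisonEntry, ...]] = {}
        for cls in doc["classes"]:
            sig = tuple(cls["signature"])
            classes[sig] = tuple(
                ComparisonEntry(
                    key=tuple(v["key"]),  # type: ignore[arg-type]
                    per_person={
                        p: _variant_from_json(obj)
                        for p, obj in v["per_person"].items()
                    },
                )
                for v in cls["variants"]
            )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed comparison JSON: {exc}") from None
    return ComparisonReport(persons=persons, classes=classes)
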