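"""Combinable facet filters and text search over reports.

Semantics (identical for single-person reports and comparisons):

* within a facet, membership in ANY selected token suffices (OR);
* across facets, EVERY nonempty facet must be satisfied (AND);
* an empty facet imposes no constraint, so the empty spec is the identity;
* search is a facet like any other: a case-insensitive substring match over
  variant name, health category, clinical importance, and effect summary.

The person facet hides non-selected persons and drops variants carried only
by hidden persons; the membership partition is recomputed over the visible
persons. The impact facet is evaluated per (variant, person) cell, because
display impact is the one per-person attribute (the same variant can be
carrier in a parent and pathogenic in a child): a person's copy of a
variant survives iff that person's display impact is selected, and the
variant survives iff any visible copy survives. This cell-level rule is
what makes facet application order-independent -- applying facets one at a
time equals applying them all at once.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ArityError, IdentityError, ValidationError
from .models import (
    AnnotatedVariant,
    Certainty,
    ComparisonEntry,
    ComparisonReport,
    DisplayImpact,
    EffectRecord,
    FilterSpec,
    PersonReport,
)

__all__ = ["apply_filter", "available_facets", "FacetInventory"]


@dataclass(frozen=True)
class FacetInventory:
    """Distinct facet values present in a view, for UI/CLI enumeration."""

    persons: frozenset[str]
    categories: frozenset[str]
    impacts: frozenset[DisplayImpact]
    certainties: frozenset[Certainty]


def _effect_matches(effect: EffectRecord, spec: FilterSpec) -> bool:
    """Variant-level facets: category, certainty, search text."""
    if spec.categories and effect.category not in spec.categories:
        return False
    if spec.certainties and effect.certainty not in spec.certainties:
        return False
    if spec.search_term:
        needle = spec.search_term.lower()
        haystacks = (
            effect.variant_name,
            effect.category,
            effect.clinical_importance,
            effect.effect_summary,
        )
        if not any(needle in h.lower() for h in haystacks):
            return False
    return True


def _copy_matches(variant: AnnotatedVariant, spec: FilterSpec) -> bool:
    """Per-person cell facet: display impact."""
    return not spec.impacts or variant.display_impact in spec.impacts


def apply_filter(view, spec: FilterSpec):
    """Filter a :class:`PersonReport` or :class:`ComparisonReport`.

    Returns a view of the same kind. A variant survives iff it satisfies
    every nonempty facet; for comparisons, the partition is recomputed over
    visible persons. Unknown persons raise :class:`IdentityError`; unknown
    impact/certainty tokens are rejected when the :class:`FilterSpec` is
    built. Category tokens and search terms are free text: an unknown one
    simply selects nothing.
    """
    if isinstance(view, PersonReport):
        return _filter_person_report(view, spec)
    if isinstance(view, ComparisonReport):
        return _filter_comparison(view, spec)
    raise TypeError(f"cannot filter {type(view).__name__}")


def _filter_person_report(report: PersonReport, spec: FilterSpec) -> PersonReport:
    if spec.persons:
        unknown = spec.persons - {report.person_id}
        if unknown:
            raise IdentityError(
                f"facet 'persons': unknown person(s) {sorted(unknown)}"
            )
    kept = tuple(
        v
        for v in report
        if _effect_matches(v.effect, spec) and _copy_matches(v, spec)
    )
    return PersonReport(person_id=report.person_id, variants=kept)


def _filter_comparison(cmp: ComparisonReport, spec: FilterSpec) -> ComparisonReport:
    if spec.persons:
        unknown = spec.persons - set(cmp.persons)
        if unknown:
            raise IdentityError(
                f"facet 'persons': unknown person(s) {sorted(unknown)}"
            )
        visible = tuple(p for p in cmp.persons if p in spec.persons)
        if len(visible) < 2:
            raise ArityError(
                "person facet must leave at least 2 visible persons"
            )
    else:
        visible = cmp.persons

    by_key: dict = {}
    order: list = []
    for _sig, entry in cmp.entries():
        if not _effect_matches(entry.effect, spec):
            continue
        surviving = {
            p: v
            for p, v in entry.per_person.items()
            if p in visible and _copy_matches(v, spec)
        }
        if not surviving:
            continue
        by_key[entry.key] = surviving
        order.append(entry.key)

    from .comparison import signature_sort_key  # shared ordering rule

    classes: dict[tuple[str, ...], list[ComparisonEntry]] = {}
    for key in order:
        per_person = by_key[key]
        sig = tuple(p for p in visible if p in per_person)
        classes.setdefault(sig, []).append(
            ComparisonEntry(key=key, per_person=per_person)
        )
    ordered = {}
    for sig in sorted(classes, key=signature_sort_key(visible)):
        entries = sorted(
            classes[sig],
            key=lambda e: (e.effect.category, e.effect.variant_name),
        )
        ordered[sig] = tuple(entries)
    return ComparisonReport(persons=visible, classes=ordered)


def available_facets(view) -> FacetInventory:
    """Enumerate the distinct persons/categories/impacts/certainties present."""
    if isinstance(view, PersonReport):
        variants = [(view.person_id, v) for v in view]
        persons = {view.person_id} if len(view) else set()
    elif isinstance(view, ComparisonReport):
        variants = [
            (p, v)
            for _sig, entry in view.entries()
            for p, v in entry.per_person.items()
        ]
        persons = {p for p, _ in variants}
    else:
        raise TypeError(f"cannot enumerate facets of {type(view).__name__}")
    return FacetInventory(
        persons=frozenset(persons),
        categories=frozenset(v.effect.category for _, v in variants),
        impacts=frozenset(v.display_impact for _, v in variants),
        certainties=frozenset(v.effect.certainty for _, v in variants),
    )


def build_filter_spec(
    persons=(),
    categories=(),
    impacts=(),
    certainties=(),
    search_term: str = "",
) -> FilterSpec:
    """Convenience constructor accepting plain strings for enum facets."""
    try:
        return FilterSpec(
            persons=frozenset(persons),
            categories=frozenset(categories),
            impacts=frozenset(impacts),
            certainties=frozenset(certainties),
            search_term=search_term,
        )
    except ValidationError:
        raise
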