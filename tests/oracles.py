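"""Independent brute-force oracles the tests check the implementation against.

Each oracle recomputes an expected result by direct enumeration or naive
set algebra, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

from itertools import chain, combinations

from variantcompare.models import (
    BaseImpact,
    DisplayImpact,
    Inheritance,
    Zygosity,
)

#: Frozen truth table for the pathogenic rows of the display-impact rule:
#: (inheritance, zygosity) -> expected display for a pathogenic base impact.
PATHOGENIC_DISPLAY_TABLE = {
    (Inheritance.RECESSIVE, Zygosity.HETEROZYGOUS): DisplayImpact.CARRIER,
    (Inheritance.RECESSIVE, Zygosity.HOMOZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.RECESSIVE, Zygosity.HEMIZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.DOMINANT, Zygosity.HETEROZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.DOMINANT, Zygosity.HOMOZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.DOMINANT, Zygosity.HEMIZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.UNKNOWN, Zygosity.HETEROZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.UNKNOWN, Zygosity.HOMOZYGOUS): DisplayImpact.PATHOGENIC,
    (Inheritance.UNKNOWN, Zygosity.HEMIZYGOUS): DisplayImpact.PATHOGENIC,
}


def display_impact_oracle(base, inheritance, zygosity):
    """Expected display impact over all 36 combinations."""
    if BaseImpact(base) is BaseImpact.PATHOGENIC:
        return PATHOGENIC_DISPLAY_TABLE[(Inheritance(inheritance), Zygosity(zygosity))]
    return DisplayImpact(BaseImpact(base).value)


def zygosity_oracle(genotype: str, risk_allele: str):
    """Expected zygosity by direct allele counting; None when absent."""
    if "-" in genotype:
        return None
    matches = sum(1 for allele in genotype if allele == risk_allele)
    return {
        (1, 1): Zygosity.HEMIZYGOUS,
        (2, 1): Zygosity.HETEROZYGOUS,
        (2, 2): Zygosity.HOMOZYGOUS,
    }.get((len(genotype), matches))


def naive_annotation_join(genotypes, kb):
    """Naive double loop: every (genotype record, KB entry) pair is tested."""
    matched = set()
    for record in genotypes:
        for effect in kb:
            if effect.rsid != record.rsid or "-" in record.genotype:
                continue
            if record.genotype.count(effect.risk_allele) >= 1:
                matched.add(effect.key)
    return matched


def powerset_classes(reports):
    """Membership classes by direct set algebra over every signature.

    class(S) = (intersection of keys over S) minus (union of keys outside S),
    for every nonempty subset S of the persons.
    """
    key_sets = {r.person_id: r.keys() for r in reports}
    persons = [r.person_id for r in reports]
    classes = {}
    for size in range(1, len(persons) + 1):
        for subset in combinations(persons, size):
            inside = set.intersection(*(key_sets[p] for p in subset))
            outside = set().union(
                *(key_sets[p] for p in persons if p not in subset)
            ) if len(subset) < len(persons) else set()
            members = inside - outside
            if members:
                classes[frozenset(subset)] = members
    return classes


def all_person_subsets(persons, min_size=2):
    return chain.from_iterable(
        combinations(persons, k) for k in range(min_size, len(persons) + 1)
    )


def filter_oracle_keys(report, spec):
    """Surviving variant keys of a single-person report by direct scan."""
    keys = set()
    for v in report:
        e = v.effect
        if spec.categories and e.category not in spec.categories:
            continue
        if spec.certainties and e.certainty not in spec.certainties:
            continue
        if spec.impacts and v.display_impact not in spec.impacts:
            continue
        if spec.search_term:
            blob = " ".join(
                (e.variant_name, e.category, e.clinical_importance, e.effect_summary)
            ).lower()
            if spec.search_term.lower() not in blob:
                continue
        keys.add(v.key)
    return keys


def interval_overlaps(intervals):
    """All-pairs check for overlapping (start, extent) intervals."""
    pairs = []
    for i, (s1, e1) in enumerate(intervals):
        for s2, e2 in intervals[i + 1:]:
            if s1 < s2 + e2 - 1e-12 and s2 < s1 + e1 - 1e-12:
                pairs.append(((s1, e1), (s2, e2)))
    return pairs
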