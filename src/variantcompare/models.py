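"""Domain model: genotypes, the variant-effect knowledge base, annotated
reports, and comparison partitions.

The unit of identity throughout is the *variant key* ``(rsid, risk_allele)``:
a reference-SNP identifier plus the allele whose presence has a known,
published effect. A person "carries" a variant when at least one of their
genotype alleles at that rsid equals the risk allele; how many copies they
carry is the zygosity, which in turn determines whether a recessive
pathogenic variant is displayed as *carrier* status.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from .errors import (
    ArityError,
    DuplicateRecordError,
    IdentityError,
    ValidationError,
)

__all__ = [
    "BaseImpact",
    "DisplayImpact",
    "Inheritance",
    "Certainty",
    "Zygosity",
    "VariantKey",
    "GenotypeRecord",
    "GenotypeSet",
    "EffectRecord",
    "EffectKB",
    "AnnotatedVariant",
    "PersonReport",
    "ComparisonEntry",
    "ComparisonReport",
    "FilterSpec",
    "VALID_CHROMOSOMES",
    "NO_CALL",
]

#: Chromosome labels accepted in consumer raw-download files.
VALID_CHROMOSOMES = frozenset(str(c) for c in range(1, 23)) | {"X", "Y", "MT"}

#: The no-call token used by consumer genotyping platforms.
NO_CALL = "--"

_GENOTYPE_ALPHABET = frozenset("ACGTID-")
_ALLELE_ALPHABET = frozenset("ACGTID")


class BaseImpact(str, enum.Enum):
    """Published effect class of a variant, before zygosity is considered."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    PROTECTIVE = "protective"
    PHARMACOGENETIC = "pharmacogenetic"


class DisplayImpact(str, enum.Enum):
    """Effect class as displayed for one person.

    Identical to :class:`BaseImpact` plus ``carrier``: a heterozygous
    recessive pathogenic variant does not affect the person themselves but
    can be transmitted to offspring.
    """

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    PROTECTIVE = "protective"
    PHARMACOGENETIC = "pharmacogenetic"
    CARRIER = "carrier"


class Inheritance(str, enum.Enum):
    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    UNKNOWN = "unknown"


class Certainty(str, enum.Enum):
    """Strength of the published evidence behind a variant's effect."""

    WELL_ESTABLISHED = "well_established"
    LIKELY = "likely"
    UNCERTAIN = "uncertain"


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"  # 1 of 2 alleles
    HOMOZYGOUS = "homozygous"      # 2 of 2 alleles
    HEMIZYGOUS = "hemizygous"      # 1 of 1 (X/Y/MT single-allele calls)


VariantKey = tuple[str, str]


@dataclass(frozen=True)
class GenotypeRecord:
    """One raw genotype call: rsid, chromosome, 1-based position, alleles."""

    rsid: str
    chromosome: str
    position: int
    genotype: str

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValidationError("rsid must be nonempty")
        if self.chromosome not in VALID_CHROMOSOMES:
            raise ValidationError(
                f"{self.rsid}: chromosome {self.chromosome!r} not in 1-22/X/Y/MT"
            )
        if self.position < 1:
            raise ValidationError(f"{self.rsid}: position must be >= 1")
        g = self.genotype
        if not g or len(g) > 2 or g != g.upper() or not set(g) <= _GENOTYPE_ALPHABET:
            raise ValidationError(
                f"{self.rsid}: genotype {g!r} must be 1-2 uppercase symbols "
                "over A/C/G/T/I/D/-"
            )

    @property
    def is_no_call(self) -> bool:
        """True if any allele is missing ('-'); '--' is the full no-call."""
        return "-" in self.genotype


@dataclass(frozen=True)
class GenotypeSet:
    """All raw genotype calls for one person, keyed by rsid."""

    person_id: str
    records: tuple[GenotypeRecord, ...]
    _index: Mapping[str, GenotypeRecord] = field(
        init=False, repr=False, compare=False, hash=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValidationError("person_id must be nonempty")
        index: dict[str, GenotypeRecord] = {}
        for rec in self.records:
            if rec.rsid in index:
                raise DuplicateRecordError(
                    f"duplicate rsid {rec.rsid} for person {self.person_id}"
                )
            index[rec.rsid] = rec
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GenotypeRecord]:
        return iter(self.records)

    def get(self, rsid: str) -> GenotypeRecord | None:
        return self._index.get(rsid)


@dataclass(frozen=True)
class EffectRecord:
    """One knowledge-base entry: a variant with a known, published effect."""

    variant_name: str
    rsid: str
    risk_allele: str
    base_impact: BaseImpact
    inheritance: Inheritance
    certainty: Certainty
    allele_frequency: float
    category: str
    clinical_importance: str = ""
    effect_summary: str = ""

    def __post_init__(self) -> None:
        if not self.variant_name:
            raise ValidationError("variant_name must be nonempty")
        if not self.rsid:
            raise ValidationError(f"{self.variant_name}: rsid must be nonempty")
        if self.risk_allele not in _ALLELE_ALPHABET:
            raise ValidationError(
                f"{self.variant_name}: risk_allele {self.risk_allele!r} "
                "must be one of A/C/G/T/I/D"
            )
        # enum coercion so callers may pass plain strings
        for fld, typ in (
            ("base_impact", BaseImpact),
            ("inheritance", Inheritance),
            ("certainty", Certainty),
        ):
            value = getattr(self, fld)
            if not isinstance(value, typ):
                try:
                    object.__setattr__(self, fld, typ(value))
                except ValueError:
                    raise ValidationError(
                        f"{self.variant_name}: {fld} {value!r} not one of "
                        f"{[m.value for m in typ]}"
                    ) from None
        if not 0.0 < self.allele_frequency <= 1.0:
            raise ValidationError(
                f"{self.variant_name}: allele_frequency "
                f"{self.allele_frequency} outside (0, 1]"
            )
        if not self.category:
            raise ValidationError(f"{self.variant_name}: category must be nonempty")

    @property
    def key(self) -> VariantKey:
        return (self.rsid, self.risk_allele)

    @property
    def gene(self) -> str:
        """Gene symbol, the prefix of a GENE-change style variant name."""
        return self.variant_name.split("-", 1)[0]


@dataclass(frozen=True)
class EffectKB:
    """The variant-effect knowledge base: the universe of known effects."""

    records: tuple[EffectRecord, ...]
    source_label: str = "synthetic"

    _index: Mapping[VariantKey, EffectRecord] = field(
        init=False, repr=False, compare=False, hash=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        index: dict[VariantKey, EffectRecord] = {}
        for rec in self.records:
            if rec.key in index:
                raise DuplicateRecordError(
                    f"duplicate knowledge-base key {rec.key}"
                )
            index[rec.key] = rec
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EffectRecord]:
        return iter(self.records)

    def get(self, key: VariantKey) -> EffectRecord | None:
        return self._index.get(key)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A knowledge-base variant observed in one person's genotypes."""

    effect: EffectRecord
    zygosity: Zygosity
    display_impact: DisplayImpact
    rarity_size: float

    def __post_init__(self) -> None:
        if not isinstance(self.zygosity, Zygosity):
            object.__setattr__(self, "zygosity", Zygosity(self.zygosity))
        if not isinstance(self.display_impact, DisplayImpact):
            object.__setattr__(
                self, "display_impact", DisplayImpact(self.display_impact)
            )
        if (
            self.display_impact is DisplayImpact.CARRIER
            and self.effect.base_impact is not BaseImpact.PATHOGENIC
        ):
            raise ValidationError(
                f"{self.effect.variant_name}: carrier display requires a "
                "pathogenic base impact"
            )
        if not 0.0 < self.rarity_size <= 1.0:
            raise ValidationError(
                f"{self.effect.variant_name}: rarity_size "
                f"{self.rarity_size} outside (0, 1]"
            )

    @property
    def key(self) -> VariantKey:
        return self.effect.key


@dataclass(frozen=True)
class PersonReport:
    """All annotated variants for one person, keyed by (rsid, risk_allele)."""

    person_id: str
    variants: tuple[AnnotatedVariant, ...]

    _index: Mapping[VariantKey, AnnotatedVariant] = field(
        init=False, repr=False, compare=False, hash=False, default=None  # type: ignore[assignment]
    )

    def __post_init__(self) -> None:
        if not self.person_id:
            raise ValidationError("person_id must be nonempty")
        index: dict[VariantKey, AnnotatedVariant] = {}
        for v in self.variants:
            if v.key in index:
                raise DuplicateRecordError(
                    f"duplicate variant key {v.key} in report for "
                    f"{self.person_id}"
                )
            index[v.key] = v
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[AnnotatedVariant]:
        return iter(self.variants)

    def keys(self) -> set[VariantKey]:
        return set(self._index)

    def get(self, key: VariantKey) -> AnnotatedVariant | None:
        return self._index.get(key)


@dataclass(frozen=True)
class ComparisonEntry:
    """One variant inside a membership class: its key plus each carrying
    person's view of it (zygosity and display impact may differ by person)."""

    key: VariantKey
    per_person: Mapping[str, AnnotatedVariant]

    @property
    def effect(self) -> EffectRecord:
        return next(iter(self.per_person.values())).effect


@dataclass(frozen=True)
class ComparisonReport:
    """Partition of the union of 2-4 person reports into membership classes.

    ``classes`` maps a membership signature -- the exact subset of persons
    carrying a variant, as a tuple ordered like ``persons`` -- to the
    variants in that class. Every variant key appears in exactly one class.
    Classes are ordered full-sharing first, then by descending signature
    size, ties broken by person order.
    """

    persons: tuple[str, ...]
    classes: Mapping[tuple[str, ...], tuple[ComparisonEntry, ...]]

    def __post_init__(self) -> None:
        if not 2 <= len(self.persons) <= 4:
            raise ArityError(
                f"comparisons take 2-4 persons, got {len(self.persons)}"
            )
        if len(set(self.persons)) != len(self.persons):
            raise IdentityError("duplicate person_id in comparison")
        seen: set[VariantKey] = set()
        for sig, entries in self.classes.items():
            if not sig or not set(sig) <= set(self.persons):
                raise IdentityError(f"invalid membership signature {sig}")
            for entry in entries:
                if entry.key in seen:
                    raise DuplicateRecordError(
                        f"variant {entry.key} appears in more than one class"
                    )
                seen.add(entry.key)

    def all_keys(self) -> set[VariantKey]:
        return {e.key for entries in self.classes.values() for e in entries}

    def keys_for(self, person: str) -> set[VariantKey]:
        """All variant keys carried by one person."""
        if person not in self.persons:
            raise IdentityError(f"unknown person {person!r}")
        return {
            e.key
            for sig, entries in self.classes.items()
            if person in sig
            for e in entries
        }

    def entries(self) -> Iterator[tuple[tuple[str, ...], ComparisonEntry]]:
        """All (signature, entry) pairs in class order."""
        for sig, class_entries in self.classes.items():
            for entry in class_entries:
                yield sig, entry


@dataclass(frozen=True)
class FilterSpec:
    """Combinable facet filters plus text search.

    Within a facet, any selected token suffices (OR); across facets, every
    nonempty facet must be satisfied (AND). An empty facet imposes no
    constraint. ``search_term`` is a case-insensitive substring match over
    variant name, category, clinical importance, and effect summary.
    """

    persons: frozenset[str] = frozenset()
    categories: frozenset[str] = frozenset()
    impacts: frozenset[DisplayImpact] = frozenset()
    certainties: frozenset[Certainty] = frozenset()
    search_term: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "persons", frozenset(self.persons))
        object.__setattr__(self, "categories", frozenset(self.categories))
        object.__setattr__(
            self, "impacts", _coerce_enum_set(self.impacts, DisplayImpact, "impacts")
        )
        object.__setattr__(
            self,
            "certainties",
            _coerce_enum_set(self.certainties, Certainty, "certainties"),
        )

    @property
    def is_empty(self) -> bool:
        return (
            not self.persons
            and not self.categories
            and not self.impacts
            and not self.certainties
            and not self.search_term
        )


def _coerce_enum_set(values: Iterable, typ, facet: str) -> frozenset:
    out = set()
    for v in values:
        if isinstance(v, typ):
            out.add(v)
        else:
            try:
                out.add(typ(v))
            except ValueError:
                raise ValidationError(
                    f"facet {facet!r}: unknown token {v!r}"
                ) from None
    return frozenset(out)
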