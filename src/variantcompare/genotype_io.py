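"""Readers and writers for the formats the tool touches.

Three formats:

* consumer raw genotype text (the 23andMe download dialect): ``#`` comment
  lines, then one call per line as four tab-separated columns
  ``rsid  chromosome  position  genotype``; the no-call token is ``--`` and
  insertion/deletion alleles are ``I``/``D``;
* the variant-effect knowledge base as CSV (one row per known effect);
* the per-person annotated report as CSV, round-trippable field-exactly.

All CSV I/O uses RFC-4180 quoting via the standard :mod:`csv` module.
"""

from __future__ import annotations

import csv
import io
from typing import IO, Iterable, Union

from .errors import (
    DuplicateRecordError,
    FormatError,
    ParseError,
    ValidationError,
)
from .models import (
    AnnotatedVariant,
    EffectKB,
    EffectRecord,
    GenotypeRecord,
    GenotypeSet,
    PersonReport,
)

Source = Union[str, IO[str]]

__all__ = [
    "read_raw_genotypes",
    "write_raw_genotypes",
    "read_effect_kb",
    "write_effect_kb",
    "read_report_csv",
    "write_report_csv",
    "KB_COLUMNS",
    "REPORT_COLUMNS",
]

#: Knowledge-base CSV header, one column per EffectRecord field.
KB_COLUMNS = (
    "variant_name",
    "rsid",
    "risk_allele",
    "base_impact",
    "inheritance",
    "certainty",
    "allele_frequency",
    "category",
    "clinical_importance",
    "effect_summary",
)

#: Per-person report CSV header. Carries the full effect record so that a
#: written report reads back field-exactly.
REPORT_COLUMNS = (
    "variant_name",
    "rsid",
    "risk_allele",
    "zygosity",
    "display_impact",
    "base_impact",
    "inheritance",
    "certainty",
    "allele_frequency",
    "rarity_size",
    "category",
    "clinical_importance",
    "effect_summary",
)


def _as_stream(source: Source) -> IO[str]:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_raw_genotypes(source: Source, person_id: str) -> GenotypeSet:
    """Parse a consumer raw genotype file into a :class:`GenotypeSet`.

    ``source`` is an open text stream or a string holding the file content.
    Comment lines start with ``#`` and are skipped; every other line must
    have exactly four tab-separated fields. Genotypes are uppercased; rsid
    order is preserved. A malformed line raises :class:`ParseError` with its
    line number; a repeated rsid raises :class:`DuplicateRecordError`
    (silently keeping one call could flip a zygosity).
    """
    records: list[GenotypeRecord] = []
    seen: set[str] = set()
    for line_no, raw in enumerate(_as_stream(source), start=1):
        line = raw.rstrip("\r\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(
                f"expected 4 tab-separated fields, got {len(fields)}", line_no
            )
        rsid, chrom, pos_text, genotype = fields
        try:
            position = int(pos_text)
        except ValueError:
            raise ParseError(f"position {pos_text!r} is not an integer", line_no)
        if rsid in seen:
            raise DuplicateRecordError(
                f"line {line_no}: duplicate rsid {rsid}"
            )
        seen.add(rsid)
        try:
            records.append(
                GenotypeRecord(
                    rsid=rsid,
                    chromosome=chrom,
                    position=position,
                    genotype=genotype.upper(),
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), line_no) from None
    return GenotypeSet(person_id=person_id, records=tuple(records))


def write_raw_genotypes(genotypes: GenotypeSet, sink: IO[str]) -> None:
    """Write a :class:`GenotypeSet` in the consumer raw dialect."""
    sink.write(f"# raw genotype calls for {genotypes.person_id}\n")
    sink.write("# rsid\tchromosome\tposition\tgenotype\n")
    for rec in genotypes:
        sink.write(f"{rec.rsid}\t{rec.chromosome}\t{rec.position}\t{rec.genotype}\n")


def read_effect_kb(source: Source, source_label: str = "csv") -> EffectKB:
    """Load the variant-effect knowledge base from CSV.

    The header must name every :data:`KB_COLUMNS` field. Each row is
    validated against the EffectRecord invariants; an unknown impact,
    inheritance, or certainty token, or an allele frequency outside (0, 1],
    raises :class:`ValidationError` naming the row. A repeated
    (rsid, risk_allele) key raises :class:`DuplicateRecordError`.
    """
    reader = csv.DictReader(_as_stream(source))
    if reader.fieldnames is None:
        raise FormatError("knowledge-base CSV is empty (no header)")
    missing = [c for c in KB_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"knowledge-base CSV missing column(s): {missing}")
    records: list[EffectRecord] = []
    for row_no, row in enumerate(reader, start=2):
        try:
            records.append(
                EffectRecord(
                    variant_name=row["variant_name"],
                    rsid=row["rsid"],
                    risk_allele=row["risk_allele"],
                    base_impact=row["base_impact"],
                    inheritance=row["inheritance"],
                    certainty=row["certainty"],
                    allele_frequency=_parse_fraction(row["allele_frequency"]),
                    category=row["category"],
                    clinical_importance=row["clinical_importance"],
                    effect_summary=row["effect_summary"],
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {row_no}: {exc}") from None
    return EffectKB(records=tuple(records), source_label=source_label)


def write_effect_kb(kb: EffectKB, sink: IO[str]) -> None:
    """Write a knowledge base as CSV (inverse of :func:`read_effect_kb`)."""
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(KB_COLUMNS)
    for rec in kb:
        writer.writerow(
            (
                rec.variant_name,
                rec.rsid,
                rec.risk_allele,
                rec.base_impact.value,
                rec.inheritance.value,
                rec.certainty.value,
                repr(rec.allele_frequency),
                rec.category,
                rec.clinical_importance,
                rec.effect_summary,
            )
        )


def write_report_csv(report: PersonReport, sink: IO[str]) -> None:
    """Write a per-person annotated report as CSV.

    The header is always written; fractions are serialized with ``repr`` so
    that write -> read round trips are field-exact.
    """
    writer = csv.writer(sink, lineterminator="\n")
    writer.writerow(REPORT_COLUMNS)
    for v in report:
        e = v.effect
        writer.writerow(
            (
                e.variant_name,
                e.rsid,
                e.risk_allele,
                v.zygosity.value,
                v.display_impact.value,
                e.base_impact.value,
                e.inheritance.value,
                e.certainty.value,
                repr(e.allele_frequency),
                repr(v.rarity_size),
                e.category,
                e.clinical_importance,
                e.effect_summary,
            )
        )


def read_report_csv(source: Source, person_id: str) -> PersonReport:
    """Read a per-person report CSV written by :func:`write_report_csv`."""
    reader = csv.DictReader(_as_stream(source))
    if reader.fieldnames is None:
        raise FormatError("report CSV is empty (no header)")
    missing = [c for c in REPORT_COLUMNS if c not in reader.fieldnames]
    if missing:
        raise FormatError(f"report CSV missing column(s): {missing}")
    variants: list[AnnotatedVariant] = []
    for row_no, row in enumerate(reader, start=2):
        try:
            effect = EffectRecord(
                variant_name=row["variant_name"],
                rsid=row["rsid"],
                risk_allele=row["risk_allele"],
                base_impact=row["base_impact"],
                inheritance=row["inheritance"],
                certainty=row["certainty"],
                allele_frequency=_parse_fraction(row["allele_frequency"]),
                category=row["category"],
                clinical_importance=row["clinical_importance"],
                effect_summary=row["effect_summary"],
            )
            variants.append(
                AnnotatedVariant(
                    effect=effect,
                    zygosity=row["zygosity"],
                    display_impact=row["display_impact"],
                    rarity_size=float(row["rarity_size"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"row {row_no}: {exc}") from None
    return PersonReport(person_id=person_id, variants=tuple(variants))


def _parse_fraction(text: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ValidationError(f"not a number: {text!r}") from None


def iter_effect_rows(records: Iterable[EffectRecord]):
    """Yield KB rows as plain dicts (handy for ad-hoc tabular export)."""
    for rec in records:
        yield {
            "variant_name": rec.variant_name,
            "rsid": rec.rsid,
            "risk_allele": rec.risk_allele,
            "base_impact": rec.base_impact.value,
            "inheritance": rec.inheritance.value,
            "certainty": rec.certainty.value,
            "allele_frequency": rec.allele_frequency,
            "category": rec.category,
            "clinical_importance": rec.clinical_importance,
            "effect_summary": rec.effect_summary,
        }
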