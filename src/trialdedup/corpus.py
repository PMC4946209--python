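"""Ingestion and consolidation of multi-registry trial registration data.

A *record* is a trial as registered in one registry; a record may have
several published *variants* (notably one per EU member state in EUCTR).
This module parses registry exports (XML or tab-delimited), strips markup,
collapses EUCTR variants onto a single record stem, and flags redacted
records whose public title is a placeholder.
"""

from __future__ import annotations

import csv
import html
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import IO, Iterable, Sequence

from lxml import etree

__all__ = [
    "RecordVariant",
    "RegistryRecord",
    "strip_html",
    "parse_corpus",
    "write_corpus",
    "consolidate_variants",
    "detect_redaction",
    "DEFAULT_REDACTION_MARKERS",
    "euctr_stem",
]

#: Public-title values that mark a record as redacted (compared after
#: trimming and case-folding).  "N/A" is used by EUCTR; the bracketed
#: device marker by ClinicalTrials.gov.
DEFAULT_REDACTION_MARKERS: tuple[str, ...] = (
    "n/a",
    "[trial of device that is not approved or cleared by the u.s. fda]",
)

_EUCTR_RE = re.compile(r"^(EUCTR\d{4}-\d{6}-\d{2})-([A-Z]{2})$")

_TAG_RE = re.compile(r"<[^<>]*>")


def euctr_stem(registry_id: str) -> tuple[str, str | None]:
    """Split an EUCTR variant id into (record stem, member-state suffix).

    ``EUCTR2011-004388-62-BE`` -> ``("EUCTR2011-004388-62", "BE")``.  Any id
    that does not carry a two-letter member-state suffix is its own stem.
    """
    m = _EUCTR_RE.match(registry_id)
    if m:
        return m.group(1), m.group(2)
    return registry_id, None


def strip_html(raw: str) -> str:
    """Remove markup tags, decode HTML entities, and collapse whitespace.

    Tag removal and entity decoding are iterated to a fixed point, so the
    function is idempotent even on nested or double-encoded input.
    """
    text = raw
    for _ in range(10):
        stripped = html.unescape(_TAG_RE.sub(" ", text))
        if stripped == text:
            break
        text = stripped
    return " ".join(text.split())


@dataclass(slots=True)
class RecordVariant:
    """One registration as published in a registry.

    ``registry_id`` is the full published id (variant suffix included for
    EUCTR); ``variant_suffix`` is the EUCTR member-state code, if any.
    Multi-valued fields keep their individual values; they are concatenated
    only when text similarity is computed.
    """

    registry_id: str
    registry: str
    public_title: str = ""
    scientific_title: str = ""
    acronym: str = ""
    secondary_ids: list[str] = field(default_factory=list)
    conditions: list[str] = field(default_factory=list)
    interventions: list[str] = field(default_factory=list)
    outcomes: list[str] = field(default_factory=list)
    inclusion_criteria: str = ""
    sponsors: list[str] = field(default_factory=list)
    date_registered: date | None = None
    date_enrolment: date | None = None
    countries: list[str] = field(default_factory=list)
    variant_suffix: str | None = None

    def __post_init__(self) -> None:
        if not self.registry_id:
            raise ValueError("registry_id must be non-empty")
        if self.variant_suffix is None:
            self.variant_suffix = euctr_stem(self.registry_id)[1]

    @property
    def record_stem(self) -> str:
        return euctr_stem(self.registry_id)[0]


@dataclass(slots=True)
class RegistryRecord:
    """A consolidated record: one chosen variant plus pooled identifiers."""

    record_id: str
    chosen_variant: RecordVariant
    variants: list[RecordVariant]
    redacted: bool = False

    @property
    def registry(self) -> str:
        return self.chosen_variant.registry

    @property
    def concatenated_title(self) -> str:
        """Public title, scientific title, and acronym joined by single
        spaces (titles and acronyms are used inconsistently between
        registries, so they are pooled before similarity scoring)."""
        parts = [
            self.chosen_variant.public_title,
            self.chosen_variant.scientific_title,
            self.chosen_variant.acronym,
        ]
        return " ".join(p for p in parts if p)

    @property
    def secondary_ids(self) -> list[str]:
        """Secondary IDs pooled over *all* variants, order-preserving."""
        seen: dict[str, None] = {}
        for v in self.variants:
            for s in v.secondary_ids:
                seen.setdefault(s, None)
        return list(seen)

    @property
    def sponsors(self) -> list[str]:
        return self.chosen_variant.sponsors

    def field_text(self, name: str) -> str:
        """Raw text of one of the five scored fields.

        ``title`` is the concatenated title; multi-valued fields are joined
        by single spaces.
        """
        v = self.chosen_variant
        if name == "title":
            return self.concatenated_title
        if name == "condition":
            return " ".join(v.conditions)
        if name == "intervention":
            return " ".join(v.interventions)
        if name == "outcome":
            return " ".join(v.outcomes)
        if name == "inclusion":
            return v.inclusion_criteria
        raise KeyError(f"unknown field {name!r}")


def detect_redaction(
    record: RegistryRecord | RecordVariant,
    markers: Sequence[str] = DEFAULT_REDACTION_MARKERS,
) -> bool:
    """True iff the public title matches a redaction marker
    (case-insensitive, after trimming)."""
    variant = record.chosen_variant if isinstance(record, RegistryRecord) else record
    title = variant.public_title.strip().casefold()
    return title in {m.strip().casefold() for m in markers}


# ---------------------------------------------------------------------------
# Parsing and writing
# ---------------------------------------------------------------------------

_LIST_FIELDS = ("secondary_ids", "conditions", "interventions", "outcomes",
                "sponsors", "countries")
_LIST_CHILD = {
    "secondary_ids": "secondary_id",
    "conditions": "condition",
    "interventions": "intervention",
    "outcomes": "outcome",
    "sponsors": "sponsor",
    "countries": "country",
}
_SCALAR_FIELDS = ("registry", "public_title", "scientific_title", "acronym",
                  "inclusion_criteria")
_DATE_FIELDS = ("date_registered", "date_enrolment")

_TSV_COLUMNS = ("registry_id", "registry", "public_title", "scientific_title",
                "acronym", "secondary_ids", "conditions", "interventions",
                "outcomes", "inclusion_criteria", "sponsors",
                "date_registered", "date_enrolment", "countries")


def _parse_date(text: str, where: str) -> date | None:
    text = text.strip()
    if not text:
        return None
    try:
        return date.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"bad date {text!r} in {where}") from exc


def _clean(text: str) -> str:
    return strip_html(text)


def _check_unique(variants: list[RecordVariant]) -> None:
    seen: set[str] = set()
    for v in variants:
        if v.registry_id in seen:
            raise ValueError(f"duplicate registry_id {v.registry_id!r} in input")
        seen.add(v.registry_id)


def _parse_xml(source: bytes | str | Path | IO[bytes]) -> list[RecordVariant]:
    if isinstance(source, (str, Path)):
        try:
            tree = etree.parse(str(source))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed XML in {source}: {exc}") from exc
        root = tree.getroot()
    else:
        data = source if isinstance(source, bytes) else source.read()
        try:
            root = etree.fromstring(data)
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"malformed XML: {exc}") from exc
    variants: list[RecordVariant] = []
    for elem in root.iter("trial"):
        rid = (elem.findtext("registry_id") or "").strip()
        if not rid:
            raise ValueError(
                f"<trial> element at line {elem.sourceline} lacks <registry_id>")
        kwargs: dict = {"registry_id": rid}
        for name in _SCALAR_FIELDS:
            kwargs[name] = _clean(elem.findtext(name) or "")
        for name in _LIST_FIELDS:
            kwargs[name] = [
                _clean(c.text or "") for c in elem.findall(_LIST_CHILD[name])
            ]
        for name in _DATE_FIELDS:
            kwargs[name] = _parse_date(elem.findtext(name) or "", f"<trial> {rid}")
        variants.append(RecordVariant(**kwargs))
    _check_unique(variants)
    return variants


def _parse_tsv(source: str | Path | IO[str]) -> list[RecordVariant]:
    if isinstance(source, (str, Path)):
        fh: IO[str] = open(source, newline="", encoding="utf-8")
        close = True
    else:
        fh, close = source, False
    try:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = set(_TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise ValueError(f"missing columns in header: {sorted(missing)}")
        variants: list[RecordVariant] = []
        for i, row in enumerate(reader, start=2):
            rid = (row["registry_id"] or "").strip()
            if not rid:
                raise ValueError(f"line {i}: empty registry_id")
            kwargs: dict = {"registry_id": rid}
            for name in _SCALAR_FIELDS:
                kwargs[name] = _clean(row[name] or "")
            for name in _LIST_FIELDS:
                raw = row[name] or ""
                kwargs[name] = [_clean(p) for p in raw.split("|") if p != ""]
            for name in _DATE_FIELDS:
                kwargs[name] = _parse_date(row[name] or "", f"line {i}")
            variants.append(RecordVariant(**kwargs))
        _check_unique(variants)
        return variants
    finally:
        if close:
            fh.close()


def parse_corpus(source, format: str = "xml") -> list[RecordVariant]:
    """Parse a registry export into a list of :class:`RecordVariant`.

    Parameters
    ----------
    source
        Path, byte string, or open file in the declared dialect.
    format
        ``"xml"`` (one ``<trial>`` element per variant) or ``"tsv"``
        (tab-separated, list fields joined by ``|``, mandatory header).

    Raises
    ------
    ValueError
        On malformed input (naming the offending element or line) or on a
        duplicate ``registry_id``.
    """
    if format == "xml":
        return _parse_xml(source)
    if format in ("tsv", "delimited"):
        return _parse_tsv(source)
    raise ValueError(f"unknown format {format!r}")


def write_corpus(variants: Iterable[RecordVariant], path, format: str = "xml") -> None:
    """Write variants in one of the two supported dialects (round-trip safe)."""
    variants = list(variants)
    if format == "xml":
        root = etree.Element("trials")
        for v in variants:
            el = etree.SubElement(root, "trial")
            etree.SubElement(el, "registry_id").text = v.registry_id
            for name in _SCALAR_FIELDS:
                etree.SubElement(el, name).text = getattr(v, name)
            for name in _LIST_FIELDS:
                for item in getattr(v, name):
                    etree.SubElement(el, _LIST_CHILD[name]).text = item
            for name in _DATE_FIELDS:
                d = getattr(v, name)
                etree.SubElement(el, name).text = d.isoformat() if d else ""
        etree.ElementTree(root).write(
            str(path), encoding="utf-8", xml_declaration=True, pretty_print=True)
    elif format in ("tsv", "delimited"):
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(_TSV_COLUMNS)
            for v in variants:
                row = []
                for name in _TSV_COLUMNS:
                    val = getattr(v, name)
                    if name in _LIST_FIELDS:
                        row.append("|".join(val))
                    elif name in _DATE_FIELDS:
                        row.append(val.isoformat() if val else "")
                    else:
                        row.append(val)
                writer.writerow(row)
    else:
        raise ValueError(f"unknown format {format!r}")


def _variant_sort_key(v: RecordVariant):
    # earliest registration wins; missing dates sort last; ties broken by
    # member-state suffix, then by full id, for determinism
    return (
        v.date_registered is None,
        v.date_registered or date.max,
        v.variant_suffix or "",
        v.registry_id,
    )


def consolidate_variants(
    variants: Iterable[RecordVariant],
    redaction_markers: Sequence[str] = DEFAULT_REDACTION_MARKERS,
) -> list[RegistryRecord]:
    """Collapse variants onto record stems, keeping the first-registered one.

    EUCTR ids lose their member-state suffix; every other registry id is its
    own record stem.  For a multi-variant record the variant with the
    earliest registration date represents the record; all variants are kept
    for secondary-ID linkage.
    """
    by_stem: dict[str, list[RecordVariant]] = {}
    for v in variants:
        by_stem.setdefault(v.record_stem, []).append(v)
    records = []
    for stem, group in by_stem.items():
        group = sorted(group, key=_variant_sort_key)
        chosen = group[0]
        rec = RegistryRecord(record_id=stem, chosen_variant=chosen, variants=group)
        rec.redacted = detect_redaction(rec, redaction_markers)
        records.append(rec)
    records.sort(key=lambda r: r.record_id)
    return records
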