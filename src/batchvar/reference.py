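"""Reference repeat unit, element annotation, known variants and exclusion mask.

All coordinates in this package are 1-based and inclusive on the single
repeat-unit reference.  Batch sequencing superimposes every copy of a
coding copy-number repeat onto one reference unit, so a variant carried by
a subset of copies appears as a low-fraction allele at a single reference
position; every downstream table is indexed by these 1-based positions.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "ReferenceRepeat",
    "AnnotationRecord",
    "KnownVariant",
    "HaplotypeDefinition",
    "ExclusionMask",
    "load_reference",
    "load_annotation",
    "write_annotation",
    "load_known_variants",
    "mask_from_annotation",
]

_DNA = set("ACGTN")
ELEMENT_TYPES = {"exon", "intron", "microsatellite", "primer", "other"}


@dataclass(frozen=True)
class ReferenceRepeat:
    """A single repeat-unit reference sequence (e.g. one 5.1 kb kringle unit)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence is empty")
        bad = set(self.sequence) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in reference: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside 1..{self.length}")
        return self.sequence[pos - 1]


@dataclass(frozen=True)
class AnnotationRecord:
    """One genetic element on the repeat unit.

    ``frame_offset`` (exons only) is the number of leading bases that
    complete a codon begun upstream -- in the previous exon, or in the
    previous repeat copy for the first coding element.  ``order_index``
    gives the concatenation order of coding elements.
    """

    element_name: str
    element_type: str
    start: int
    end: int
    frame_offset: int | None = None
    order_index: int | None = None

    def __post_init__(self) -> None:
        if self.element_type not in ELEMENT_TYPES:
            raise ValueError(f"unknown element type {self.element_type!r}")
        if self.start > self.end:
            raise ValueError(
                f"{self.element_name}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValueError(f"{self.element_name}: start {self.start} < 1")
        if self.element_type == "exon":
            if self.frame_offset not in (0, 1, 2):
                raise ValueError(
                    f"{self.element_name}: exon frame_offset must be 0, 1 or 2"
                )

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class KnownVariant:
    """A single-base difference expected from repeat-subtype superposition,
    or any other curated variant (position, ref, alt, free-text label)."""

    pos: int
    ref: str
    alt: str
    label: str = ""
    alias: str | None = None

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError(f"pos {self.pos}: ref equals alt ({self.ref})")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass
class HaplotypeDefinition:
    """A named set of variants expected to co-occur on one repeat molecule.

    ``canonical_subset`` lists the positions whose joint presence defines
    carrier status for the subtype (three exonic positions for KIV-2B).
    """

    name: str
    variants: list[KnownVariant] = field(default_factory=list)
    canonical_subset: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        positions = [v.pos for v in self.variants]
        if len(positions) != len(set(positions)):
            raise ValueError(f"{self.name}: duplicate positions in definition")
        extra = set(self.canonical_subset) - set(positions)
        if extra:
            raise ValueError(f"{self.name}: canonical positions {sorted(extra)} not in variant list")

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(v.pos for v in self.variants)


@dataclass(frozen=True)
class ExclusionMask:
    """Intervals (1-based inclusive) excluded from all variant calling,
    e.g. the central microsatellite of the repeat."""

    intervals: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if start > end or start < 1:
                raise ValueError(f"bad mask interval ({start}, {end})")

    def contains(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.intervals)

    def positions(self) -> set[int]:
        out: set[int] = set()
        for s, e in self.intervals:
            out.update(range(s, e + 1))
        return out

    def validate_against(self, reference: ReferenceRepeat) -> None:
        for s, e in self.intervals:
            if e > reference.length:
                raise ValueError(
                    f"mask interval ({s}, {e}) exceeds reference length {reference.length}"
                )


def load_reference(path: str | Path) -> ReferenceRepeat:
    """Load the single repeat-unit reference from a FASTA file.

    The file must hold exactly one record; the sequence is uppercased.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise ValueError(f"{path}: multiple reference records ({len(records)}); expected one")
    rec = records[0]
    return ReferenceRepeat(name=rec.id, sequence=str(rec.seq).upper())


_ANNOTATION_COLUMNS = ["name", "type", "start", "end", "frame_offset", "order_index"]


def _parse_optional_int(text: str, what: str) -> int | None:
    text = text.strip()
    if text in ("", "."):
        return None
    try:
        return int(text)
    except ValueError as exc:
        raise ValueError(f"bad {what} value {text!r}") from exc


def load_annotation(
    path: str | Path,
    reference: ReferenceRepeat | None = None,
) -> list[AnnotationRecord]:
    """Read the tab-delimited element annotation.

    Columns: name, type, start, end, frame_offset, order_index.  Missing
    values are written as '.'; lines starting with '#' are comments.  When a
    reference is supplied, element bounds are validated against its length
    and same-type elements are checked for overlap.
    """
    records: list[AnnotationRecord] = []
    with open(path, newline="") as handle:
        reader = csv.reader(
            (line for line in handle if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty annotation file")
        header = [h.strip() for h in header]
        if header[: len(_ANNOTATION_COLUMNS)] != _ANNOTATION_COLUMNS:
            raise ValueError(
                f"{path}: annotation header must start with {_ANNOTATION_COLUMNS}, got {header}"
            )
        for row in reader:
            if len(row) < 4:
                raise ValueError(f"{path}: short row {row}")
            name, etype = row[0].strip(), row[1].strip()
            start, end = int(row[2]), int(row[3])
            frame = _parse_optional_int(row[4], "frame_offset") if len(row) > 4 else None
            order = _parse_optional_int(row[5], "order_index") if len(row) > 5 else None
            records.append(
                AnnotationRecord(
                    element_name=name,
                    element_type=etype,
                    start=start,
                    end=end,
                    frame_offset=frame,
                    order_index=order,
                )
            )
    _check_same_type_overlap(records)
    if reference is not None:
        for rec in records:
            if rec.end > reference.length:
                raise ValueError(
                    f"{rec.element_name}: end {rec.end} exceeds reference length {reference.length}"
                )
    return records


def _check_same_type_overlap(records: Sequence[AnnotationRecord]) -> None:
    by_type: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_type.setdefault(rec.element_type, []).append(rec)
    for etype, recs in by_type.items():
        recs = sorted(recs, key=lambda r: r.start)
        for a, b in zip(recs, recs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"overlapping {etype} elements {a.element_name} and {b.element_name}"
                )


def write_annotation(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    """Write annotation records back to TSV, field-for-field."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANNOTATION_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.element_name,
                    rec.element_type,
                    rec.start,
                    rec.end,
                    "." if rec.frame_offset is None else rec.frame_offset,
                    "." if rec.order_index is None else rec.order_index,
                ]
            )


def mask_from_annotation(records: Iterable[AnnotationRecord]) -> ExclusionMask:
    """Build the exclusion mask from all microsatellite elements."""
    return ExclusionMask(
        intervals=tuple(
            (r.start, r.end) for r in records if r.element_type == "microsatellite"
        )
    )


_KNOWN_COLUMNS = ["pos", "ref", "alt", "label"]


def load_known_variants(
    path: str | Path,
    reference: ReferenceRepeat | None = None,
    haplotype_name: str = "KIV-2B",
    canonical_tag: str = "canonical",
) -> tuple[HaplotypeDefinition, list[KnownVariant]]:
    """Read the tab-delimited known-variant / haplotype-definition file.

    Columns: pos, ref, alt, label[, alias].  Every ref base is checked
    against the reference sequence when one is supplied.  Rows whose label
    contains ``canonical_tag`` (case-insensitive) form the canonical subset
    whose joint presence defines subtype carrier status.

    Returns the haplotype definition plus the flat variant list.
    """
    variants: list[KnownVariant] = []
    with open(path, newline="") as handle:
        reader = csv.reader(
            (line for line in handle if line.strip() and not line.startswith("#")),
            delimiter="\t",
        )
        header = next(reader, None)
        if header is not None:
            header = [h.strip() for h in header]
            if header[: len(_KNOWN_COLUMNS)] != _KNOWN_COLUMNS:
                raise ValueError(
                    f"{path}: known-variant header must start with {_KNOWN_COLUMNS}"
                )
        for row in reader:
            pos = int(row[0])
            ref, alt = row[1].strip().upper(), row[2].strip().upper()
            label = row[3].strip() if len(row) > 3 else ""
            alias = row[4].strip() if len(row) > 4 and row[4].strip() not in ("", ".") else None
            if reference is not None and reference.base(pos) != ref:
                raise ValueError(
                    f"{path}: ref mismatch at position {pos}: file says {ref}, "
                    f"reference has {reference.base(pos)}"
                )
            variants.append(KnownVariant(pos=pos, ref=ref, alt=alt, label=label, alias=alias))
    canonical = frozenset(
        v.pos for v in variants if canonical_tag.lower() in v.label.lower()
    )
    definition = HaplotypeDefinition(
        name=haplotype_name, variants=variants, canonical_subset=canonical
    )
    return definition, variants
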