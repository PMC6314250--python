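"""Element context, amino-acid consequence and known-variant labels for calls.

Translation convention: the first codon fully encoded inside the repeat's
first coding exon is residue 1 (the preceding partial codon is completed
by the upstream repeat copy and is therefore unknown to a single-unit
analysis).  This shifts residue numbering by -1 relative to schemes that
count the upstream-spanning codon as residue 1.  The trailing partial
codon at the repeat's 3' coding boundary is completed by wrap-around with
the repeat's own leading coding bases (repeat periodicity), so the last
codon exists but is flagged boundary-spanning.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .caller import VariantCall
from .reference import AnnotationRecord, KnownVariant, ReferenceRepeat

__all__ = [
    "AnnotatedCall",
    "Location",
    "locate",
    "amino_acid_change",
    "flag_known",
    "annotate_calls",
    "write_report",
]

NEAR_SPLICE_BP = 25

_TYPE_PRIORITY = {"exon": 0, "microsatellite": 1, "primer": 2, "intron": 3, "other": 4}


class Location(NamedTuple):
    element_name: str
    element_type: str
    splice_distance: int | None
    near_splice: bool
    canonical_splice: bool


@dataclass(frozen=True)
class AnnotatedCall:
    call: VariantCall
    element_name: str
    element_type: str
    coding: bool
    codon_index: int | None
    aa_change: str | None
    splice_distance: int | None
    near_splice: bool
    canonical_splice: bool
    known_label: str
    boundary_spanning: bool = False


def locate(
    pos: int,
    annotations: Sequence[AnnotationRecord],
    near_splice_bp: int = NEAR_SPLICE_BP,
) -> Location:
    """Containing element and signed distance to the nearest exon boundary.

    Distance is negative upstream of an exon start, positive past an exon
    end, and 0 inside an exon.  Positions at +-1/+-2 of a boundary are the
    canonical splice sites.
    """
    containing = [rec for rec in annotations if rec.contains(pos)]
    if containing:
        element = min(containing, key=lambda r: _TYPE_PRIORITY.get(r.element_type, 9))
        name, etype = element.element_name, element.element_type
    else:
        name, etype = "intergenic", "other"

    exons = [rec for rec in annotations if rec.element_type == "exon"]
    distance: int | None = None
    if exons:
        best: int | None = None
        for exon in exons:
            if exon.contains(pos):
                best = 0
                break
            d = pos - exon.start if pos < exon.start else pos - exon.end
            if best is None or abs(d) < abs(best):
                best = d
        distance = best
    near = distance is not None and abs(distance) <= near_splice_bp
    canonical = distance is not None and abs(distance) in (1, 2)
    return Location(name, etype, distance, near, canonical)


def _coding_stream(
    reference: ReferenceRepeat, annotations: Sequence[AnnotationRecord]
) -> tuple[list[int], int]:
    """Concatenated coding positions (1-based) in translation order, plus
    the first element's frame offset."""
    exons = [r for r in annotations if r.element_type == "exon"]
    if not exons:
        raise ValueError("no exon records in annotation")
    exons.sort(key=lambda r: (r.order_index if r.order_index is not None else r.start))
    positions: list[int] = []
    for exon in exons:
        positions.extend(range(exon.start, exon.end + 1))
    offset = exons[0].frame_offset or 0
    if len(positions) - offset < 3:
        raise ValueError("coding length after frame offset is shorter than one codon")
    return positions, offset


def amino_acid_change(
    call: VariantCall,
    reference: ReferenceRepeat,
    annotations: Sequence[AnnotationRecord],
) -> tuple[str, int, bool]:
    """Amino-acid consequence of a coding call.

    Returns (change, codon_index, boundary_spanning) where change is
    "synonymous" or "p.(RefPosAlt)" with "Ter" for stop codons.
    """
    positions, offset = _coding_stream(reference, annotations)
    try:
        stream_idx = positions.index(call.pos)
    except ValueError as exc:
        raise ValueError(f"position {call.pos} is not coding") from exc
    if stream_idx < offset:
        # leading bases complete a codon begun in the upstream repeat copy;
        # by periodicity it is the same codon as the boundary-spanning last
        # codon of this unit
        stream_idx += len(positions)
    idx = stream_idx - offset
    codon_index = idx // 3 + 1
    codon_start = codon_index * 3 - 3

    coding_positions = positions[offset:] + positions[:offset]  # wrap-around
    codon_pos = coding_positions[codon_start : codon_start + 3]
    if len(codon_pos) < 3:
        raise ValueError(
            f"incomplete terminal codon at position {call.pos}: coding length "
            "is not a multiple of 3 even after wrap-around"
        )
    boundary = any(p in positions[:offset] for p in codon_pos)
    ref_codon = "".join(reference.base(p) for p in codon_pos)
    alt_codon = "".join(
        call.alt if p == call.pos else reference.base(p) for p in codon_pos
    )
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if ref_aa == alt_aa:
        return "synonymous", codon_index, boundary
    return (
        f"p.({seq3(ref_aa)}{codon_index}{seq3(alt_aa)})",
        codon_index,
        boundary,
    )


def flag_known(
    call: VariantCall, known_variants: Iterable[KnownVariant]
) -> str:
    """Label of the exact (pos, ref, alt) match among known variants, or
    "novel".  Matching is allele-specific: a different alt at a known
    position is still novel."""
    for kv in known_variants:
        if kv.key == (call.pos, call.ref, call.alt):
            return kv.label or "known"
    return "novel"


def annotate_calls(
    calls: Iterable[VariantCall],
    reference: ReferenceRepeat,
    annotations: Sequence[AnnotationRecord],
    known_variants: Sequence[KnownVariant] = (),
    near_splice_bp: int = NEAR_SPLICE_BP,
) -> list[AnnotatedCall]:
    """Attach element context, consequence and known-variant label to every
    call.  Annotation is total: every call receives exactly one element and
    one label."""
    known_index = {kv.key: (kv.label or "known") for kv in known_variants}
    out: list[AnnotatedCall] = []
    for call in calls:
        loc = locate(call.pos, annotations, near_splice_bp)
        coding = loc.element_type == "exon"
        aa: str | None = None
        codon_index: int | None = None
        boundary = False
        if coding:
            aa, codon_index, boundary = amino_acid_change(call, reference, annotations)
        label = known_index.get((call.pos, call.ref, call.alt), "novel")
        out.append(
            AnnotatedCall(
                call=call,
                element_name=loc.element_name,
                element_type=loc.element_type,
                coding=coding,
                codon_index=codon_index,
                aa_change=aa,
                splice_distance=loc.splice_distance,
                near_splice=loc.near_splice,
                canonical_splice=loc.canonical_splice,
                known_label=label,
                boundary_spanning=boundary,
            )
        )
    return out


_REPORT_COLUMNS = [
    "sample", "pos", "ref", "alt", "level", "level_fwd", "level_rev",
    "depth_total", "depth_fwd", "depth_rev", "lrt_fwd", "lrt_rev",
    "filter", "multiallelic", "element_name", "element_type", "coding",
    "codon_index", "aa_change", "splice_distance", "near_splice",
    "canonical_splice", "known_label",
]


def write_report(
    annotated: Iterable[AnnotatedCall], path: str | Path, sample: str = "sample"
) -> None:
    """Tabular annotated variant report; one row per (sample, pos, alt)."""

    def fmt(x) -> str:
        return "." if x is None else str(x)

    with open(path, "w") as out:
        out.write("\t".join(_REPORT_COLUMNS) + "\n")
        for a in annotated:
            c = a.call
            row = [
                sample, c.pos, c.ref, c.alt, f"{c.level:.6f}",
                f"{c.level_fwd:.6f}", f"{c.level_rev:.6f}", c.depth_total,
                c.depth_fwd, c.depth_rev, f"{c.lrt_fwd:.4f}", f"{c.lrt_rev:.4f}",
                c.filter, int(c.multiallelic), a.element_name, a.element_type,
                int(a.coding), fmt(a.codon_index), fmt(a.aa_change),
                fmt(a.splice_distance), int(a.near_splice),
                int(a.canonical_splice), a.known_label,
            ]
            out.write("\t".join(str(x) for x in row) + "\n")
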