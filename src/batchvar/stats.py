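"""Supporting statistics: two-sample proportion test, rank-based
inverse-normal transform, GC content, and degenerate restriction-site
scanning (e.g. DraIII)."""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy.stats import chi2, norm, rankdata

__all__ = [
    "ProportionTestResult",
    "MotifHit",
    "prop_test_2sample",
    "inverse_normal",
    "gc_content",
    "scan_degenerate_sites",
    "variant_site_effect",
    "RESTRICTION_ENZYMES",
]

#: recognition motifs of the named enzymes used in repeat-polymorphism work
RESTRICTION_ENZYMES: dict[str, str] = {
    "DraIII": "CACNNNGTG",
}


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    chi_square: float
    p_value: float
    corrected: bool


def prop_test_2sample(
    x1: int, n1: int, x2: int, n2: int, correction: bool = True
) -> ProportionTestResult:
    """Two-sample test for equality of proportions (pooled chi-square).

    With ``correction`` a Yates continuity correction is applied, capped so
    the corrected difference never crosses zero; this reproduces the
    standard R ``prop.test`` behaviour.  The p-value is two-sided from
    chi-square with one degree of freedom.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("sample sizes must be positive")
        if not 0 <= x <= n:
            raise ValueError(f"count {x} outside 0..{n}")
    observed = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = observed.sum(axis=1, keepdims=True)
    col = observed.sum(axis=0, keepdims=True)
    expected = row * col / observed.sum()
    yates = min(0.5, abs(observed[0, 0] - expected[0, 0])) if correction else 0.0
    stat = float((((np.abs(observed - expected) - yates) ** 2) / expected).sum())
    p = float(chi2.sf(stat, df=1))
    return ProportionTestResult(x1, n1, x2, n2, stat, p, correction)


def inverse_normal(values: Sequence[float], c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform, Phi^-1((rank - c)/(n - 2c + 1)).

    ``c`` is the Blom offset (3/8 by default); ties receive average ranks.
    Used to normalise highly skewed outcome distributions before linear
    modelling.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values")
    if np.unique(arr).size < 2:
        raise ValueError("constant vector cannot be inverse-normal transformed")
    ranks = rankdata(arr, method="average")
    return norm.ppf((ranks - c) / (arr.size - 2.0 * c + 1.0))


def gc_content(sequence: str) -> float:
    """GC percentage of a DNA string; N is excluded from both numerator
    and denominator."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    counted = [b for b in seq if b in "ACGT"]
    if not counted:
        raise ValueError("no unambiguous bases in sequence")
    gc = sum(1 for b in counted if b in "GC")
    return 100.0 * gc / len(counted)


class MotifHit(NamedTuple):
    motif: str
    start: int  # 1-based position of the leftmost base on the forward strand
    strand: str


def _iupac_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        if ch not in ambiguous_dna_values:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        opts = ambiguous_dna_values[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def scan_degenerate_sites(sequence: str, motif: str) -> list[MotifHit]:
    """All matches of an IUPAC motif on both strands, overlaps included.

    Reverse-strand hits are reported by the 1-based forward-strand position
    of their leftmost base; a site matched identically on both strands
    (palindromic recognition) is reported once, on the forward strand.
    """
    seq = sequence.upper()
    pattern = re.compile(f"(?=({_iupac_regex(motif)}))")
    rc_motif = str(Seq(motif.upper()).reverse_complement())
    rc_pattern = re.compile(f"(?=({_iupac_regex(rc_motif)}))")
    hits: dict[tuple[int, int], MotifHit] = {}
    for m in pattern.finditer(seq):
        start = m.start() + 1
        hits[(start, start + len(motif) - 1)] = MotifHit(motif, start, "+")
    for m in rc_pattern.finditer(seq):
        start = m.start() + 1
        key = (start, start + len(motif) - 1)
        if key not in hits:
            hits[key] = MotifHit(motif, start, "-")
    return sorted(hits.values(), key=lambda h: (h.start, h.strand))


def variant_site_effect(
    sequence: str, pos: int, ref: str, alt: str, motif: str
) -> str:
    """Classify a single-base variant as creating, destroying, or not
    touching recognition sites of ``motif``.

    Returns "creates", "destroys" or "none" by comparing the hit sets of
    the original and mutated sequence.
    """
    seq = sequence.upper()
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside sequence")
    if seq[pos - 1] != ref.upper():
        raise ValueError(
            f"ref mismatch at {pos}: sequence has {seq[pos - 1]}, variant says {ref}"
        )
    mutated = seq[: pos - 1] + alt.upper() + seq[pos:]
    before = {(h.start, h.strand) for h in scan_degenerate_sites(seq, motif)}
    after = {(h.start, h.strand) for h in scan_degenerate_sites(mutated, motif)}
    if after - before:
        return "creates"
    if before - after:
        return "destroys"
    return "none"
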