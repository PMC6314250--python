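"""In-silico two-haplotype amplicon mixture benchmark.

Emulates the calibration design for batch sequencing of a copy-number
repeat: two repeat haplotypes (A = reference, B differing at K known
positions, including runs of adjacent differences as real subtypes show)
are mixed at a defined ratio, amplified with an optional per-haplotype
amplification-bias factor, and sequenced with Phred-calibrated per-base
substitution errors on both strands.  Reads are emitted pre-aligned (their
true positions are known), so no external aligner is needed; the variant
caller is then scored against the planted truth.

The bias factor beta models differential amplification efficiency of the
minor haplotype: a template fraction x is observed as
x' = beta*x / (beta*x + 1 - x).  beta = 1 is unbiased; beta < 1
underamplifies the minor component, pushing low-level variants below the
caller's hard floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .caller import CallerConfig, VariantCall, call_sample
from .pileup import FilterConfig, build_pileup
from .reference import ExclusionMask, KnownVariant, ReferenceRepeat

__all__ = [
    "MixtureSpec",
    "TruthSet",
    "BenchmarkMetrics",
    "STANDARD_MIX_FRACTIONS",
    "synthetic_reference",
    "make_haplotypes",
    "observed_fraction",
    "simulate_reads",
    "write_sam",
    "write_fastq",
    "evaluate",
    "estimate_bias",
    "run_benchmark",
]

#: the benchmark mixing ratios (minor-haplotype fractions): 50:50 .. 99:1
STANDARD_MIX_FRACTIONS = (0.5, 0.10, 0.05, 0.025, 0.015, 0.01)

#: number of haplotype-B-specific differences planted by default
DEFAULT_K = 60

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_IDX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i


@dataclass(frozen=True)
class TruthSet:
    """Planted haplotype-B-specific differences and their expected level."""

    records: tuple[tuple[int, str, str], ...]
    expected_level: float | None = None

    def __post_init__(self) -> None:
        positions = [r[0] for r in self.records]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate positions in truth set")

    @property
    def positions(self) -> frozenset[int]:
        return frozenset(r[0] for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class MixtureSpec:
    """Configuration of one simulated mixture sequencing run."""

    reference: ReferenceRepeat
    haplotype_b_variants: list[KnownVariant]
    mix_fraction: float = 0.5
    coverage_per_strand: int = 500
    base_quality: int | Sequence[int] = 30
    amplification_bias: float = 1.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mix_fraction <= 1.0:
            raise ValueError("mix_fraction must be in [0, 1]")
        if self.coverage_per_strand < 1:
            raise ValueError("coverage must be >= 1")
        if self.amplification_bias <= 0:
            raise ValueError("amplification_bias must be positive")

    @property
    def observed_mix_fraction(self) -> float:
        return observed_fraction(self.mix_fraction, self.amplification_bias)


@dataclass(frozen=True)
class BenchmarkMetrics:
    """Precision = 100*TP/(TP+FP); sensitivity = 100*TP/K; specificity =
    100*TN/(N-K) with N the callable (unmasked) positions and the
    negatives counted per position."""

    tp: int
    fp: int
    fn: int
    tn: int
    negatives: int

    @property
    def precision(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.negatives if self.negatives else float("nan")

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def observed_fraction(x: float, beta: float) -> float:
    """Bias-adjusted observed minor-haplotype fraction
    x' = beta*x / (beta*x + 1 - x)."""
    if x == 0.0:
        return 0.0
    return beta * x / (beta * x + 1.0 - x)


def synthetic_reference(
    length: int = 5104, seed: int = 0, name: str = "repeat_unit", gc: float = 0.44
) -> ReferenceRepeat:
    """Random synthetic repeat-unit reference with the region's typical
    GC content (~44%)."""
    rng = np.random.default_rng(seed)
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    idx = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    seq = _BASES[idx].tobytes().decode("ascii")
    return ReferenceRepeat(name=name, sequence=seq)


def make_haplotypes(
    reference: ReferenceRepeat,
    k: int = DEFAULT_K,
    seed: int = 0,
    mask: ExclusionMask | None = None,
) -> tuple[str, str, TruthSet]:
    """Haplotype pair differing at exactly ``k`` unmasked positions.

    Haplotype A is the reference itself; haplotype B carries ``k`` planted
    single-base differences including at least one run of 2-5 consecutive
    differences, emulating the clustered adjacent differences real repeat
    subtypes show (the pattern BAQ recalibration destroys).
    """
    mask = mask or ExclusionMask()
    masked = mask.positions()
    unmasked = [p for p in range(1, reference.length + 1) if p not in masked]
    if k > len(unmasked):
        raise ValueError(f"k={k} exceeds {len(unmasked)} unmasked positions")
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    if k >= 2:
        run_len = int(rng.integers(2, min(5, k) + 1))
        starts = [
            p
            for p in unmasked
            if all((p + i) not in masked and p + i <= reference.length for i in range(run_len))
        ]
        run_start = int(rng.choice(starts))
        chosen.update(run_start + i for i in range(run_len))
    remaining = [p for p in unmasked if p not in chosen]
    extra = rng.choice(len(remaining), size=k - len(chosen), replace=False)
    chosen.update(remaining[i] for i in extra)
    positions = sorted(chosen)
    hap_b = bytearray(reference.sequence.encode("ascii"))
    records = []
    for pos in positions:
        ref_base = reference.base(pos)
        alts = [b for b in "ACGT" if b != ref_base]
        alt = alts[int(rng.integers(0, 3))]
        hap_b[pos - 1] = ord(alt)
        records.append((pos, ref_base, alt))
    return reference.sequence, hap_b.decode("ascii"), TruthSet(records=tuple(records))


def _quality_vector(base_quality: int | Sequence[int], read_length: int) -> np.ndarray:
    if isinstance(base_quality, (int, np.integer)):
        return np.full(read_length, int(base_quality), dtype=np.int16)
    q = np.asarray(base_quality, dtype=np.int16)
    if q.size != read_length:
        raise ValueError("per-cycle quality profile length must equal read length")
    return q


def _sam_header(reference: ReferenceRepeat) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": reference.name, "LN": reference.length}],
        }
    )


def simulate_reads(spec: MixtureSpec) -> tuple[list[pysam.AlignedSegment], pysam.AlignmentHeader]:
    """Simulate one mixture sequencing run as pre-aligned SAM records.

    Reads are fixed-length, tiled uniformly over the repeat, balanced
    across strands; each read is drawn from haplotype B with the
    bias-adjusted probability x' and from A otherwise, then subjected to
    per-base substitution errors at the Phred-implied rate (uniform over
    the three alternative bases).  Deterministic for a given spec + seed.
    """
    ref = spec.reference
    hap_a, hap_b, _ = _haplotype_arrays(spec)
    read_length = min(spec.read_length, ref.length)
    # starts range over [-(rl-1), L-1] and reads are clipped at the unit
    # boundaries, so every position is covered by exactly rl start offsets
    # and the depth profile is flat across the whole unit
    n_starts = ref.length + read_length - 1
    n_per_strand = int(np.ceil(spec.coverage_per_strand * n_starts / read_length))
    n_reads = 2 * n_per_strand
    rng = np.random.default_rng(spec.seed)

    starts = rng.integers(-(read_length - 1), ref.length, size=n_reads)
    is_rev = np.zeros(n_reads, dtype=bool)
    is_rev[n_per_strand:] = True
    from_b = rng.random(n_reads) < spec.observed_mix_fraction

    pos_matrix = starts[:, None] + np.arange(read_length)[None, :]
    clipped = np.clip(pos_matrix, 0, ref.length - 1)
    bases = np.where(from_b[:, None], hap_b[clipped], hap_a[clipped])

    quals = _quality_vector(spec.base_quality, read_length)
    err_prob = 10.0 ** (-quals / 10.0)
    err_mask = rng.random((n_reads, read_length)) < err_prob[None, :]
    shifts = rng.integers(1, 4, size=int(err_mask.sum()))
    bases[err_mask] = (bases[err_mask] + shifts) % 4

    header = _sam_header(ref)
    qual_arr = quals.astype(np.uint8)
    seq_bytes = _BASES[bases]
    reads: list[pysam.AlignedSegment] = []
    full_cigar = ((0, read_length),)
    full_quals = qual_arr.tolist()
    for i in range(n_reads):
        s = int(starts[i])
        left = max(0, -s)
        right = read_length - max(0, s + read_length - ref.length)
        a = pysam.AlignedSegment(header)
        a.query_name = f"sim{spec.seed}_{i}"
        if left == 0 and right == read_length:
            a.query_sequence = seq_bytes[i].tobytes().decode("ascii")
            a.cigartuples = full_cigar
            qual = full_quals
            a.reference_start = s
        else:
            a.query_sequence = seq_bytes[i, left:right].tobytes().decode("ascii")
            a.cigartuples = ((0, right - left),)
            qual = qual_arr[left:right].tolist()
            a.reference_start = s + left
        a.flag = 16 if is_rev[i] else 0
        a.reference_id = 0
        a.mapping_quality = 60
        a.query_qualities = qual
        reads.append(a)
    return reads, header


def _haplotype_arrays(spec: MixtureSpec) -> tuple[np.ndarray, np.ndarray, TruthSet]:
    ref_idx = _BASE_TO_IDX[
        np.frombuffer(spec.reference.sequence.encode("ascii"), dtype=np.uint8)
    ].astype(np.int64)
    if (ref_idx < 0).any():
        raise ValueError("reference contains non-ACGT bases; simulator requires ACGT")
    hap_b = ref_idx.copy()
    records = []
    for v in spec.haplotype_b_variants:
        if spec.reference.base(v.pos) != v.ref:
            raise ValueError(f"haplotype variant ref mismatch at {v.pos}")
        hap_b[v.pos - 1] = "ACGT".index(v.alt)
        records.append((v.pos, v.ref, v.alt))
    truth = TruthSet(records=tuple(records), expected_level=spec.observed_mix_fraction)
    return ref_idx, hap_b, truth


def truth_from_spec(spec: MixtureSpec) -> TruthSet:
    """Ground-truth variant list with the bias-adjusted expected level."""
    return _haplotype_arrays(spec)[2]


def write_sam(
    reads: Iterable[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | Path,
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            out.write(read)


def write_fastq(reads: Iterable[pysam.AlignedSegment], path: str | Path) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.query_qualities)
            out.write(f"@{read.query_name}\n{read.query_sequence}\n+\n{qual}\n")


def evaluate(
    calls: Sequence[VariantCall],
    truth: TruthSet,
    callable_positions: Iterable[int],
    require_pass: bool = False,
) -> BenchmarkMetrics:
    """Score calls against the planted truth, allele-exact.

    ``callable_positions`` are the unmasked reference positions considered;
    negatives are those not in the truth set, and a negative position
    counts against specificity when any false call is emitted there.
    """
    callable_set = set(int(p) for p in callable_positions)
    if not callable_set:
        raise ValueError("empty callable set")
    truth_keys = {(p, a) for p, _r, a in truth.records}
    truth_positions = truth.positions
    used = [
        c
        for c in calls
        if c.pos in callable_set and (c.is_pass or not require_pass)
    ]
    tp = sum(1 for c in used if (c.pos, c.alt) in truth_keys)
    false_calls = [c for c in used if (c.pos, c.alt) not in truth_keys]
    fn = len([1 for p in truth_positions if p in callable_set]) - tp
    negatives = callable_set - truth_positions
    fp = len(false_calls)
    fp_positions = {c.pos for c in false_calls if c.pos in negatives}
    tn = len(negatives) - len(fp_positions)
    return BenchmarkMetrics(tp=tp, fp=fp, fn=fn, tn=tn, negatives=len(negatives))


def estimate_bias(observed_levels: Sequence[float], mix_fraction: float) -> float:
    """Invert the bias transform from observed levels at truth positions.

    The mean called level across the planted positions estimates x'; the
    amplification-bias factor is beta = x'(1-x) / (x(1-x'))."""
    if not 0.0 < mix_fraction < 1.0:
        raise ValueError("mix_fraction must be in (0, 1) to estimate bias")
    x_obs = float(np.mean(observed_levels))
    if not 0.0 < x_obs < 1.0:
        raise ValueError("mean observed level must be in (0, 1)")
    return x_obs * (1.0 - mix_fraction) / (mix_fraction * (1.0 - x_obs))


def run_benchmark(
    spec: MixtureSpec,
    mask: ExclusionMask | None = None,
    filter_config: FilterConfig | None = None,
    caller_config: CallerConfig | None = None,
) -> tuple[BenchmarkMetrics, list[VariantCall], TruthSet]:
    """Simulate one mixture, run the full no-BAQ pipeline, score it.

    Returns the metrics, the emitted calls and the truth set.
    """
    mask = mask or ExclusionMask()
    reads, _header = simulate_reads(spec)
    pileup = build_pileup(reads, spec.reference, filter_config, mask)
    calls = call_sample(pileup, spec.reference, caller_config)
    truth = truth_from_spec(spec)
    callable_positions = [
        p for p in range(1, spec.reference.length + 1) if not mask.contains(p)
    ]
    metrics = evaluate(calls, truth, callable_positions)
    return metrics, calls, truth
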