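"""Per-site maximum-likelihood detection of low-fraction variant alleles.

In batch sequencing every repeat copy is superimposed on one reference
unit, so a variant carried by a single copy among ~80 appears at a ~1.2%
allele fraction -- the same regime as mitochondrial heteroplasmy.  Each
site is modelled per strand: a read showing base ``b`` with error
probability ``e`` (from its Phred quality) contributes

    P(b = minor) = f(1-e) + (1-f) e/3
    P(b = major) = (1-f)(1-e) + f e/3
    P(other)     = e/3

where ``f`` is the minor-allele (variant) fraction.  The fraction is
estimated by maximising the log-likelihood on [0, 1]; the evidence against
f = 0 is a likelihood-ratio statistic D = 2(ll(f_hat) - ll(0)) compared to
a chi-square(1) quantile, separately on each strand, so a variant must be
confirmed in both read directions.  Candidates below a hard 1% combined
level are pruned outright: one mutant copy among 80 repeats sits at 1.2%,
so nothing real is expected below the floor and specificity is preferred
over sensitivity there.  A 1%-level variant additionally needs 780x total
filtered coverage to be flagged PASS rather than LOW_COVERAGE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, fisher_exact

from .pileup import BASES, PileupSite, PileupTable
from .reference import ReferenceRepeat

__all__ = [
    "CallerConfig",
    "VariantCall",
    "site_loglik",
    "mle_level",
    "strand_bias_test",
    "call_site",
    "call_sample",
    "write_variant_tsv",
]

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class CallerConfig:
    #: hard lower bound on the combined variant level; candidates below are pruned
    level_floor: float = 0.01
    #: minimum total (both-strand) filtered coverage for a PASS at the floor level
    min_total_coverage_for_pass: int = 780
    #: minimum variant-supporting reads required on *each* strand
    per_strand_min_alt_reads: int = 2
    #: per-strand significance of the likelihood-ratio test against f=0
    lrt_alpha: float = 0.01
    #: Fisher exact p below which a site is a strand-bias candidate ...
    strand_bias_fisher_p: float = 1e-3
    #: ... combined with this bound on the ratio of per-strand levels
    strand_bias_level_ratio: float = 5.0
    #: optimiser tolerance for the level MLE
    optimizer_tol: float = 1e-6
    #: emit strand-biased candidates with a STRAND_BIAS flag instead of dropping
    keep_strand_biased: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.level_floor < 1.0:
            raise ValueError("level_floor must be in (0, 1)")
        if self.min_total_coverage_for_pass < 1:
            raise ValueError("min_total_coverage_for_pass must be >= 1")

    @property
    def lrt_critical(self) -> float:
        return float(chi2.ppf(1.0 - self.lrt_alpha, df=1))


@dataclass(frozen=True)
class VariantCall:
    pos: int
    ref: str
    alt: str
    level: float
    level_fwd: float
    level_rev: float
    lrt_fwd: float
    lrt_rev: float
    depth_fwd: int
    depth_rev: int
    multiallelic: bool = False
    filter_flags: tuple[str, ...] = ("PASS",)

    @property
    def depth_total(self) -> int:
        return self.depth_fwd + self.depth_rev

    @property
    def filter(self) -> str:
        return ";".join(self.filter_flags)

    @property
    def is_pass(self) -> bool:
        return self.filter_flags == ("PASS",)


# -- likelihood model ------------------------------------------------------


def _group_observations(
    observations: Sequence[tuple[str, float]]
) -> list[tuple[str, float, int]]:
    groups: dict[tuple[str, float], int] = {}
    for base, e in observations:
        if not 0.0 < e <= 1.0:
            raise ValueError(f"error probability {e} outside (0, 1]")
        groups[(base, e)] = groups.get((base, e), 0) + 1
    return [(b, e, n) for (b, e), n in groups.items()]


def _loglik_grouped(
    groups: Sequence[tuple[str, float, int]], major: str, minor: str, f: float
) -> float:
    ll = 0.0
    for base, e, n in groups:
        if base == minor:
            p = f * (1.0 - e) + (1.0 - f) * e / 3.0
        elif base == major:
            p = (1.0 - f) * (1.0 - e) + f * e / 3.0
        else:
            p = e / 3.0
        ll += n * math.log(p)
    return ll


def site_loglik(
    observations: Sequence[tuple[str, float]], major: str, minor: str, f: float
) -> float:
    """Log-likelihood of a minor-allele fraction ``f`` given base
    observations ``(base, error_probability)``."""
    if not observations:
        raise ValueError("empty observation list")
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction {f} outside [0, 1]")
    return _loglik_grouped(_group_observations(observations), major, minor, f)


def _mle_grouped(
    groups: Sequence[tuple[str, float, int]],
    major: str,
    minor: str,
    tol: float = 1e-6,
) -> tuple[float, float]:
    def nll(f: float) -> float:
        return -_loglik_grouped(groups, major, minor, f)

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded", options={"xatol": tol})
    candidates = [(0.0, -nll(0.0)), (float(res.x), -res.fun), (1.0, -nll(1.0))]
    f_hat, ll_hat = max(candidates, key=lambda c: c[1])
    d = 2.0 * (ll_hat - (-nll(0.0)))
    return f_hat, max(d, 0.0)


def mle_level(
    observations: Sequence[tuple[str, float]], major: str, minor: str, tol: float = 1e-6
) -> tuple[float, float]:
    """Maximum-likelihood minor-allele fraction and its likelihood-ratio
    statistic D = 2(ll(f_hat) - ll(0)) against f = 0."""
    if not observations:
        raise ValueError("empty observation list")
    return _mle_grouped(_group_observations(observations), major, minor, tol)


# -- filters ---------------------------------------------------------------


def strand_bias_test(
    ref_fwd: int,
    ref_rev: int,
    alt_fwd: int,
    alt_rev: int,
    fisher_p_threshold: float = 1e-3,
    level_ratio_bound: float = 5.0,
) -> tuple[float, bool]:
    """Two-sided Fisher exact test on the strand x allele 2x2 table.

    A site is flagged biased only when the table is significant *and* the
    per-strand alt fractions differ by more than ``level_ratio_bound``
    fold, so that mere depth imbalance does not trip the filter.
    """
    table = np.array([[ref_fwd, alt_fwd], [ref_rev, alt_rev]])
    if table.sum() == 0:
        return 1.0, False
    _, p = fisher_exact(table, alternative="two-sided")
    eps = 1e-12
    f_fwd = alt_fwd / max(ref_fwd + alt_fwd, 1)
    f_rev = alt_rev / max(ref_rev + alt_rev, 1)
    ratio = max(f_fwd, f_rev) / max(min(f_fwd, f_rev), eps)
    return float(p), bool(p < fisher_p_threshold and ratio > level_ratio_bound)


# -- per-site calling ------------------------------------------------------


def call_site(
    site: PileupSite, ref_base: str, config: CallerConfig | None = None
) -> list[VariantCall]:
    """Test every candidate non-reference allele at one pileup site.

    A candidate needs ``per_strand_min_alt_reads`` supporting reads on each
    strand, a significant likelihood-ratio statistic on each strand, and a
    combined level at or above the hard floor; surviving candidates are
    screened for strand bias.  Two or more emitted alleles at the position
    mark all of them multiallelic.
    """
    config = config or CallerConfig()
    if site.masked:
        raise ValueError(f"site {site.pos} is masked; masked sites are never called")
    if ref_base not in _BASE_INDEX:
        return []
    ref_idx = _BASE_INDEX[ref_base]
    counts_fwd = site.base_counts("+")
    counts_rev = site.base_counts("-")
    depth_fwd, depth_rev = int(counts_fwd.sum()), int(counts_rev.sum())
    if depth_fwd == 0 or depth_rev == 0:
        return []
    groups_fwd = site.grouped_observations("+")
    groups_rev = site.grouped_observations("-")
    crit = config.lrt_critical
    calls: list[VariantCall] = []
    for alt_idx, alt in enumerate(BASES):
        if alt_idx == ref_idx:
            continue
        alt_fwd, alt_rev = int(counts_fwd[alt_idx]), int(counts_rev[alt_idx])
        if min(alt_fwd, alt_rev) < config.per_strand_min_alt_reads:
            continue
        gf = [(BASES[b], e, n) for b, e, n in groups_fwd]
        gr = [(BASES[b], e, n) for b, e, n in groups_rev]
        f_fwd, d_fwd = _mle_grouped(gf, ref_base, alt, config.optimizer_tol)
        f_rev, d_rev = _mle_grouped(gr, ref_base, alt, config.optimizer_tol)
        if d_fwd < crit or d_rev < crit:
            continue
        level = (depth_fwd * f_fwd + depth_rev * f_rev) / (depth_fwd + depth_rev)
        if level < config.level_floor:
            continue  # hard floor: pruned, never emitted
        flags: list[str] = []
        _, biased = strand_bias_test(
            depth_fwd - alt_fwd,
            depth_rev - alt_rev,
            alt_fwd,
            alt_rev,
            config.strand_bias_fisher_p,
            config.strand_bias_level_ratio,
        )
        if biased:
            if not config.keep_strand_biased:
                continue
            flags.append("STRAND_BIAS")
        if depth_fwd + depth_rev < config.min_total_coverage_for_pass:
            flags.append("LOW_COVERAGE")
        calls.append(
            VariantCall(
                pos=site.pos,
                ref=ref_base,
                alt=alt,
                level=level,
                level_fwd=f_fwd,
                level_rev=f_rev,
                lrt_fwd=d_fwd,
                lrt_rev=d_rev,
                depth_fwd=depth_fwd,
                depth_rev=depth_rev,
                filter_flags=tuple(flags) if flags else ("PASS",),
            )
        )
    if len(calls) >= 2:
        calls = [replace(c, multiallelic=True) for c in calls]
    return sorted(calls, key=lambda c: c.alt)


def call_sample(
    pileup: PileupTable,
    reference: ReferenceRepeat | None = None,
    config: CallerConfig | None = None,
) -> list[VariantCall]:
    """Call every unmasked position of the pileup; deterministic order
    (position, then alt base)."""
    config = config or CallerConfig()
    reference = reference or pileup.reference
    calls: list[VariantCall] = []
    for pos in pileup.candidate_positions(config.per_strand_min_alt_reads):
        site = pileup.site(int(pos))
        calls.extend(call_site(site, reference.base(int(pos)), config))
    return sorted(calls, key=lambda c: (c.pos, c.alt))


_REPORT_COLUMNS = [
    "sample", "pos", "ref", "alt", "level", "level_fwd", "level_rev",
    "depth_total", "depth_fwd", "depth_rev", "lrt_fwd", "lrt_rev",
    "filter", "multiallelic",
]


def write_variant_tsv(
    calls: Iterable[VariantCall], path: str | Path, sample: str = "sample"
) -> None:
    """Write the variant report TSV (stable column order)."""
    with open(path, "w") as out:
        out.write("\t".join(_REPORT_COLUMNS) + "\n")
        for c in calls:
            out.write(
                f"{sample}\t{c.pos}\t{c.ref}\t{c.alt}\t{c.level:.6f}\t"
                f"{c.level_fwd:.6f}\t{c.level_rev:.6f}\t{c.depth_total}\t"
                f"{c.depth_fwd}\t{c.depth_rev}\t{c.lrt_fwd:.4f}\t{c.lrt_rev:.4f}\t"
                f"{c.filter}\t{int(c.multiallelic)}\n"
            )
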