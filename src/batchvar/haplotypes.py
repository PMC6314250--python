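"""Sample-level repeat-subtype analytics.

A repeat subtype (KIV-2B) is defined by three canonical exonic changes
that travel together on one molecule; a sample is a carrier when all
three are present, irrespective of their levels.  Because two of the
three positions are shared with a further subtype (KIV-2C), the level at
the shared positions is the sum of both subtypes while the third position
reports the B subtype alone; the difference, scaled by the genome-wide
repeat count, estimates the number of C-type repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .reference import HaplotypeDefinition

__all__ = [
    "SampleLevels",
    "CarrierStatus",
    "kiv2b_carrier",
    "estimate_repeats",
    "kiv2c_excess",
    "summarize_levels",
]

KIV2C_EXCESS_THRESHOLD = 0.8


@dataclass
class SampleLevels:
    """Per-sample combined variant levels keyed by position, plus the
    optional total repeat count (e.g. a qPCR estimate of summed copies)."""

    sample: str
    levels: dict[int, float] = field(default_factory=dict)
    total_repeats: float | None = None

    def __post_init__(self) -> None:
        for pos, lvl in self.levels.items():
            if not 0.0 <= lvl <= 1.0:
                raise ValueError(f"{self.sample}: level {lvl} at {pos} outside [0, 1]")
        if self.total_repeats is not None and self.total_repeats <= 0:
            raise ValueError(f"{self.sample}: total_repeats must be positive")


@dataclass(frozen=True)
class CarrierStatus:
    sample: str
    carrier: bool
    canonical_levels: tuple[float | None, ...]
    kiv2c_repeats: float = 0.0
    kiv2c_flag: bool = False


def kiv2b_carrier(levels: SampleLevels, defs: HaplotypeDefinition) -> CarrierStatus:
    """Carrier status: true iff *all* canonical positions carry a call,
    without any grouping based on variant level."""
    canonical = sorted(defs.canonical_subset)
    if len(canonical) != 3:
        raise ValueError(
            f"{defs.name}: carrier status needs 3 canonical positions, got {len(canonical)}"
        )
    observed = tuple(levels.levels.get(pos) for pos in canonical)
    return CarrierStatus(
        sample=levels.sample,
        carrier=all(v is not None for v in observed),
        canonical_levels=observed,
    )


def estimate_repeats(level: float, total_repeats: float) -> float:
    """Number of repeat copies carrying a variant: level x total copies.

    E.g. one mutant copy among 80 repeats shows a 1.25% level."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"level {level} outside [0, 1]")
    if total_repeats is None or total_repeats <= 0:
        raise ValueError("total_repeats must be a positive number")
    return level * total_repeats


def kiv2c_excess(
    levels: Mapping[int, float],
    canonical_positions: Iterable[int],
    total_repeats: float,
    threshold: float = KIV2C_EXCESS_THRESHOLD,
) -> tuple[float, bool]:
    """Estimated C-type repeat count from the level excess of the two
    shared canonical positions over the B-only position.

    ``canonical_positions`` are the three canonical positions in reference
    order; the first two are shared between subtypes, the third is
    B-specific.  The excess is clipped at zero (more C than B at the
    shared sites cannot be negative dosage) and flagged when above
    ``threshold`` repeats.
    """
    pos = sorted(canonical_positions)
    if len(pos) != 3:
        raise ValueError("exactly three canonical positions required")
    shared = [levels.get(p, 0.0) for p in pos[:2]]
    b_only = levels.get(pos[2], 0.0)
    excess_level = max(0.0, float(np.mean(shared)) - b_only)
    repeats = estimate_repeats(min(excess_level, 1.0), total_repeats)
    return repeats, repeats > threshold


def summarize_levels(
    samples: Iterable[SampleLevels],
    canonical_positions: Iterable[int],
    populations: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Group-wise level distribution summaries per canonical position.

    Returns a tidy frame with columns (population, pos, n, median, q1, q3).
    Samples without a call at a position contribute a 0 level (absence of
    the subtype variant, not missing data).  Empty groups are omitted.
    """
    positions = sorted(canonical_positions)
    rows = []
    for s in samples:
        pop = populations.get(s.sample, "all") if populations else "all"
        for pos in positions:
            rows.append((pop, pos, s.levels.get(pos, 0.0)))
    if not rows:
        return pd.DataFrame(columns=["population", "pos", "n", "median", "q1", "q3"])
    df = pd.DataFrame(rows, columns=["population", "pos", "level"])
    out = (
        df.groupby(["population", "pos"], sort=True)["level"]
        .agg(
            n="count",
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
    )
    return out
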