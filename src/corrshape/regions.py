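"""Analysis-region segmentation and before/after-treatment period mapping.

A recording is partitioned into half-open analysis regions ``[start, end)``
within which one full set of correlograms is built.  Regions either tile
the recording automatically at a fixed length (trailing remainder shorter
than one region is dropped) or are supplied manually with labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import TreatmentEvent

__all__ = [
    "AnalysisRegion",
    "PeriodAssignment",
    "auto_regions",
    "manual_regions",
    "assign_periods",
]


@dataclass(frozen=True)
class AnalysisRegion:
    """One half-open time window ``[start, end)``; ``index`` is 1-based."""

    index: int
    start: float
    end: float
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.index}: start must precede end")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PeriodAssignment:
    """Mapping region index -> period label (e.g. ``after:bicuculline``)."""

    mapping: dict

    def period_of(self, region_index: int) -> str:
        return self.mapping[region_index]

    @property
    def periods(self) -> list[str]:
        """Distinct period labels, ordered by first region."""
        seen: list[str] = []
        for idx in sorted(self.mapping):
            lab = self.mapping[idx]
            if lab not in seen:
                seen.append(lab)
        return seen


def auto_regions(duration: float, region_length: float) -> list[AnalysisRegion]:
    """Tile ``[0, duration)`` with fixed-length regions; drop the remainder.

    Region k covers ``[k*L, (k+1)*L)``; the count is ``floor(duration/L)``
    (e.g. a 20.5 h recording at 7 min regions yields 175).
    """
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    if region_length > duration:
        raise ValueError("recording shorter than one region")
    n = math.floor(duration / region_length + 1e-9)
    return [
        AnalysisRegion(k + 1, k * region_length, (k + 1) * region_length)
        for k in range(n)
    ]


def manual_regions(bounds) -> list[AnalysisRegion]:
    """Build labelled regions from (start, end, label) triples.

    Bounds may be given in any order; they are sorted by start and
    re-indexed 1..R.  Overlaps or inverted bounds are errors.
    """
    triples = sorted(bounds, key=lambda b: b[0])
    regions = []
    for i, (start, end, label) in enumerate(triples):
        if not start < end:
            raise ValueError(f"inverted region bounds ({start}, {end})")
        if i and start < triples[i - 1][1]:
            raise ValueError(
                f"overlapping regions near t={start} ({label!r})"
            )
        regions.append(AnalysisRegion(i + 1, float(start), float(end), label))
    return regions


def assign_periods(
    regions: list[AnalysisRegion], treatments: list[TreatmentEvent]
) -> PeriodAssignment:
    """Label each region before/after the treatments.

    A region is ``after:X`` iff treatment X's time falls strictly before the
    region's end — so the region containing (or starting exactly at) the
    treatment is grouped with "after".  With multiple treatments the latest
    applicable label wins.  With no treatments every region is ``all``.
    """
    treatments = sorted(treatments, key=lambda ev: ev.time)
    for ev in treatments:
        if ev.time < 0:
            raise ValueError(f"treatment {ev.label!r} before t=0")
    mapping = {}
    for region in regions:
        if not treatments:
            mapping[region.index] = "all"
            continue
        applicable = [ev for ev in treatments if ev.time < region.end]
        if applicable:
            mapping[region.index] = f"after:{applicable[-1].label}"
        else:
            mapping[region.index] = f"before:{treatments[0].label}"
    return PeriodAssignment(mapping)
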