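"""Correlogram-independent recording statistics.

Firing counts (optionally normalized per period to spikes/minute),
interspike-interval histograms on log-spaced bins, and per-minute
population rate traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Recording, SpikeTrain
from .regions import AnalysisRegion, PeriodAssignment

__all__ = ["IsiHistogram", "RateTrace", "firing_counts", "isi_histogram", "rate_trace"]

#: default log10-spaced ISI binning: 50 bins over 0.1 ms .. 1000 s
DEFAULT_ISI_RANGE = (1e-4, 1e3)
DEFAULT_ISI_BINS = 50


@dataclass(frozen=True)
class IsiHistogram:
    """Probability-normalized interspike-interval histogram (log-spaced)."""

    unit_id: str            # a unit_id or "pooled"
    bin_edges: np.ndarray   # seconds, strictly increasing, len = n_bins + 1
    probs: np.ndarray       # per-bin probability, sums to 1

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin centers (natural for log-spaced edges)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])


@dataclass(frozen=True)
class RateTrace:
    """Per-unit spike counts in consecutive 1-minute windows."""

    counts: pd.DataFrame    # rows = unit_id, columns = window index
    mean: np.ndarray        # population mean count per window
    sd: np.ndarray          # sample SD (ddof=1) per window, 0 if N == 1


def firing_counts(
    rec: Recording,
    regions: list[AnalysisRegion] | None = None,
    periods: PeriodAssignment | None = None,
) -> pd.DataFrame:
    """Events per unit, per period, with spikes-per-minute normalization.

    Without regions/periods, a single period "all" covering the full
    recording is used, so counts equal train lengths.  Units with zero
    events in a period are still reported.
    """
    if regions is None:
        spans: dict[str, list[tuple[float, float]]] = {
            "all": [(0.0, rec.duration)]
        }
    else:
        if periods is None:
            spans = {"all": [(r.start, r.end) for r in regions]}
        else:
            spans = {}
            for region in regions:
                lab = periods.period_of(region.index)
                spans.setdefault(lab, []).append((region.start, region.end))
    rows = []
    for label, windows in spans.items():
        dur_min = sum(end - start for start, end in windows) / 60.0
        if dur_min <= 0:
            raise ValueError(f"period {label!r} has zero duration")
        for train in rec.trains:
            count = sum(train.in_window(s, e).size for s, e in windows)
            rows.append(
                {
                    "unit_id": train.unit_id,
                    "period": label,
                    "count": int(count),
                    "spikes_per_min": count / dur_min,
                }
            )
    return pd.DataFrame(rows)


def _intervals(train: SpikeTrain) -> np.ndarray:
    return np.diff(train.times) if len(train) >= 2 else np.empty(0)


def isi_histogram(
    trains: SpikeTrain | list[SpikeTrain],
    n_bins: int = DEFAULT_ISI_BINS,
    isi_range: tuple[float, float] = DEFAULT_ISI_RANGE,
) -> IsiHistogram:
    """Histogram of successive within-unit intervals on log10-spaced bins.

    Intervals outside ``isi_range`` (including exact-duplicate timestamps,
    i.e. zero ISIs) are clipped into the end bins; the result is normalized
    to probability.
    """
    if isinstance(trains, SpikeTrain):
        trains = [trains]
    isis = np.concatenate([_intervals(t) for t in trains]) if trains else np.empty(0)
    if isis.size == 0:
        raise ValueError("no intervals: every train has fewer than 2 events")
    lo, hi = isi_range
    edges = np.logspace(math.log10(lo), math.log10(hi), n_bins + 1)
    clipped = np.clip(isis, lo, np.nextafter(hi, 0))
    counts, _ = np.histogram(clipped, bins=edges)
    probs = counts / counts.sum()
    uid = trains[0].unit_id if len(trains) == 1 else "pooled"
    return IsiHistogram(uid, edges, probs)


def rate_trace(rec: Recording, window: float = 60.0) -> RateTrace:
    """Per-unit spike counts per minute with population mean and SD.

    Window k covers ``[60k, 60(k+1))``; SD uses denominator N-1 and is 0
    for a single unit.
    """
    if rec.duration < window:
        raise ValueError("recording shorter than one rate window")
    n_win = max(1, math.ceil(rec.duration / window))
    edges = np.arange(n_win + 1) * window
    table = {
        t.unit_id: np.histogram(t.times, bins=edges)[0] for t in rec.trains
    }
    counts = pd.DataFrame.from_dict(table, orient="index", columns=range(n_win))
    arr = counts.to_numpy(dtype=float)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(n_win)
    return RateTrace(counts, mean, sd)
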