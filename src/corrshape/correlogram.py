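"""Correlogram construction for signal pairs within an analysis region.

A correlogram is the histogram of relative timings ``t = t_c - t_r``
between every comparison event ``t_c`` and every reference event ``t_r``
whose lag falls inside the binned lag window (half-width R, bin width w,
assignable lags ``|t| <= R + w/2``).  Normalized by its total it is
the conditional probability ``C(x)`` of a comparison event at lag ``x``
given a reference event at 0.  The center bin always sits at lag 0, so a
range of ±1 s at 1 ms bin width yields 2,001 bins.

Bin assignment is nearest-center with exact half-edge ties resolved toward
zero: at 1 ms width a lag of +2.5 ms falls in bin 2, a lag of -6.5 ms in
bin -6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import Recording, SpikeTrain
from .regions import AnalysisRegion

__all__ = [
    "CorrelogramSpec",
    "Correlogram",
    "make_bins",
    "assign_bin",
    "build_correlogram",
    "correlogram_set",
    "is_sparse",
    "EXCLUDED",
]

#: sentinel returned by assign_bin for lags beyond the assignable range
EXCLUDED = None


@dataclass(frozen=True)
class CorrelogramSpec:
    """Binning geometry for correlograms.

    ``range_s`` is the half-width R of the lag window (lags in [-R, +R]);
    ``bin_width_s`` is w.  The bin count is the odd 2*round(R/w)+1 with the
    center bin at lag 0.  ``reference_subset`` optionally restricts which
    units serve as reference rasters (perievent-style analysis).
    """

    range_s: float = 1.0
    bin_width_s: float = 0.001
    reference_subset: tuple | None = None

    def __post_init__(self) -> None:
        if self.range_s <= 0 or self.bin_width_s <= 0:
            raise ValueError("range_s and bin_width_s must be positive")
        if self.bin_width_s > 2 * self.range_s:
            raise ValueError("bin width exceeds the full lag window")
        if self.n_bins < 3:
            raise ValueError("derived bin count < 3; widen range or narrow bins")

    @property
    def half_bins(self) -> int:
        """K: number of bins on each side of the center bin."""
        return int(round(self.range_s / self.bin_width_s))

    @property
    def n_bins(self) -> int:
        return 2 * self.half_bins + 1


@dataclass(frozen=True)
class Correlogram:
    """Binned relative-timing histogram for one (reference, comparison) pair."""

    ref_id: str
    cmp_id: str
    region_index: int
    bin_centers: np.ndarray
    counts: np.ndarray          # non-negative ints, len == n_bins
    n_ref: int                  # reference events in the region
    n_cmp: int                  # comparison events in the region

    @property
    def total(self) -> int:
        """S: sum of bin counts (comparison events that landed in range)."""
        return int(self.counts.sum())

    @property
    def n_pairs(self) -> int:
        return self.n_ref * self.n_cmp

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def probs(self) -> np.ndarray | None:
        """C(x) = counts / total; None (undefined) for empty correlograms."""
        total = self.total
        if total == 0:
            return None
        return self.counts / total

    @property
    def is_auto(self) -> bool:
        return self.ref_id == self.cmp_id


def make_bins(spec: CorrelogramSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and centers for a spec; centers at k*w for k = -K..K."""
    w, K = spec.bin_width_s, spec.half_bins
    centers = np.arange(-K, K + 1) * w
    edges = (np.arange(-K, K + 2) - 0.5) * w
    return edges, centers


def assign_bin(lag: float, bin_width: float):
    """Signed bin index for a lag: nearest center, half-edge ties toward 0.

    Returns :data:`EXCLUDED` is never produced here (range filtering is the
    caller's job); the rule itself is total.  Examples at 1 ms width:
    +2.5 ms -> 2, -6.5 ms -> -6, 0 -> 0.
    """
    return int(_assign_bins_vec(np.array([float(lag)]), bin_width)[0])


#: relative tolerance for recognizing a lag sitting exactly on a bin edge
_EDGE_RTOL = 1e-9


def _assign_bins_vec(lags: np.ndarray, bin_width: float) -> np.ndarray:
    q = np.abs(lags) / bin_width
    # recognize half-integer quotients (bin edges) despite float rounding
    half_units = np.rint(2 * q)
    on_edge = np.abs(2 * q - half_units) <= _EDGE_RTOL * (1 + 2 * q)
    odd = on_edge & (half_units.astype(np.int64) % 2 == 1)
    k = np.floor(q + 0.5)
    k[odd] = (half_units[odd] - 1) // 2  # tie on an edge: toward zero
    even = on_edge & ~odd
    k[even] = half_units[even] // 2      # exactly on a center
    return np.where(lags >= 0, k, -k).astype(np.int64)


def _pair_lags(
    ref: np.ndarray, cmp: np.ndarray, limit: float, auto: bool
) -> np.ndarray:
    """All lags t_c - t_r with |lag| <= limit; self-pairs excluded when auto."""
    if ref.size == 0 or cmp.size == 0:
        return np.empty(0)
    lo = np.searchsorted(cmp, ref - limit, side="left")
    hi = np.searchsorted(cmp, ref + limit, side="right")
    spans = hi - lo
    total = int(spans.sum())
    if total == 0:
        return np.empty(0)
    # gather cmp indices for each ref window without a Python loop per pair
    offsets = np.repeat(hi - np.cumsum(spans), spans)
    cmp_idx = np.arange(total) + offsets
    ref_idx = np.repeat(np.arange(ref.size), spans)
    lags = cmp[cmp_idx] - ref[ref_idx]
    if auto:
        lags = lags[cmp_idx != ref_idx]
    return lags


def build_correlogram(
    ref: SpikeTrain,
    cmp: SpikeTrain,
    spec: CorrelogramSpec,
    region: AnalysisRegion,
) -> Correlogram:
    """Histogram of lags between all in-region event pairs within range.

    Only events with ``region.start <= time < region.end`` participate;
    pairs spanning a region boundary are not counted.  A pair contributes
    iff its lag assigns to one of the 2K+1 bins, i.e. |lag| <= R + w/2:
    the outermost bins keep their full width, so independent signals give
    a genuinely flat correlogram.  For autocorrelograms (ref is cmp) the
    pairing of an event with itself is excluded; coincident events of
    different units are included.
    """
    _, centers = make_bins(spec)
    ref_t = ref.in_window(region.start, region.end)
    cmp_t = cmp.in_window(region.start, region.end)
    auto = ref.unit_id == cmp.unit_id
    limit = spec.range_s + spec.bin_width_s / 2
    lags = _pair_lags(ref_t, cmp_t, limit, auto)
    counts = np.zeros(spec.n_bins, dtype=np.int64)
    if lags.size:
        idx = _assign_bins_vec(lags, spec.bin_width_s)
        idx = idx[np.abs(idx) <= spec.half_bins] + spec.half_bins
        np.add.at(counts, idx, 1)
    return Correlogram(
        ref_id=ref.unit_id,
        cmp_id=cmp.unit_id,
        region_index=region.index,
        bin_centers=centers,
        counts=counts,
        n_ref=int(ref_t.size),
        n_cmp=int(cmp_t.size),
    )


def correlogram_set(
    rec: Recording, region: AnalysisRegion, spec: CorrelogramSpec
) -> list[Correlogram]:
    """Correlograms for all (ref, cmp) unit pairs in one region.

    References are restricted to ``spec.reference_subset`` when given.
    Units silent in the region still yield (empty, total 0) correlograms so
    downstream matrices stay N x N.
    """
    refs = rec.trains
    if spec.reference_subset is not None:
        subset = set(spec.reference_subset)
        refs = [t for t in rec.trains if t.unit_id in subset]
    return [
        build_correlogram(r, c, spec, region) for r in refs for c in rec.trains
    ]


def is_sparse(cg: Correlogram, threshold: int = 0) -> bool:
    """True when a correlogram is too sparse for shape metrics.

    Sparse iff the product of reference and comparison event counts is at
    most ``threshold``, or the correlogram is empty (total 0).  At the
    default threshold 0 every non-empty correlogram is analyzed.
    """
    if threshold < 0:
        raise ValueError("sparsity threshold must be >= 0")
    return cg.n_pairs <= threshold or cg.total == 0
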