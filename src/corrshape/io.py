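"""Reading, validating and cleaning multi-unit spike rasters.

The native interchange format is a long CSV with header ``unit_id,time_s``
and one firing event per row.  Vendor formats (e.g. Plexon .plx) are not
parsed here; see :func:`register_adapter` for plugging in an external
reader that returns the same :class:`Recording` contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpikeTrain",
    "TreatmentEvent",
    "CleaningSpec",
    "Recording",
    "read_raster_csv",
    "write_raster_csv",
    "apply_cleaning",
    "active_unit_mask",
    "register_adapter",
    "load_recording",
]


class RasterFormatError(ValueError):
    """Raised when an input raster file violates the CSV contract."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted firing-event times (seconds) of one recorded signal/unit."""

    unit_id: str
    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if not self.unit_id:
            raise ValueError("unit_id must be a nonempty string")
        if t.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if t.size and not np.all(np.isfinite(t)):
            raise ValueError(f"unit {self.unit_id!r}: non-finite event time")
        if t.size and t.min() < 0:
            raise ValueError(f"unit {self.unit_id!r}: negative event time")
        if t.size and np.any(np.diff(t) < 0):
            object.__setattr__(self, "times", np.sort(t))

    def __len__(self) -> int:
        return int(self.times.size)

    def in_window(self, start: float, end: float) -> np.ndarray:
        """Event times inside the half-open window ``[start, end)``."""
        lo, hi = np.searchsorted(self.times, [start, end], side="left")
        return self.times[lo:hi]


@dataclass(frozen=True)
class TreatmentEvent:
    """A labelled experimental treatment administered at ``time`` seconds."""

    time: float
    label: str


@dataclass(frozen=True)
class CleaningSpec:
    """Events/units to discard before analysis.

    ``excluded_windows`` are half-open ``[start, end)`` intervals whose
    events are dropped (the absolute clock is preserved — no re-basing);
    ``removed_units`` are unit_ids dropped entirely.
    """

    excluded_windows: tuple = ()
    removed_units: tuple = ()

    def __post_init__(self) -> None:
        for start, end in self.excluded_windows:
            if not (0 <= start < end):
                raise ValueError(f"invalid excluded window [{start}, {end})")


@dataclass(frozen=True)
class Recording:
    """A collection of spike trains with a duration and treatment events."""

    trains: tuple
    duration: float
    treatments: tuple = ()
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", tuple(self.trains))
        object.__setattr__(self, "treatments", tuple(self.treatments))
        if len(self.trains) < 1:
            raise ValueError("a Recording needs at least one SpikeTrain")
        ids = [t.unit_id for t in self.trains]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique within a Recording")
        tmax = max((t.times[-1] for t in self.trains if len(t)), default=0.0)
        if self.duration < tmax:
            raise ValueError(
                f"duration {self.duration} < latest event time {tmax}"
            )
        for ev in self.treatments:
            if not (0 <= ev.time <= self.duration):
                raise ValueError(f"treatment {ev.label!r} outside recording")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def unit_ids(self) -> list[str]:
        return [t.unit_id for t in self.trains]

    def train(self, unit_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.unit_id == unit_id:
                return t
        raise KeyError(unit_id)


def read_raster_csv(path: str | Path, duration: float | None = None) -> Recording:
    """Read a long-format raster CSV into a :class:`Recording`.

    Row order in the file is irrelevant: times are sorted per unit, so the
    Recording is a canonical form.  ``duration`` defaults to the latest
    event time.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"unit_id": str})
    except pd.errors.EmptyDataError:
        raise RasterFormatError(f"{path}: no events") from None
    if list(df.columns[:2]) != ["unit_id", "time_s"]:
        raise RasterFormatError(
            f"{path}: expected header 'unit_id,time_s', got {list(df.columns)}"
        )
    if df.empty:
        raise RasterFormatError(f"{path}: no events")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = ~np.isfinite(times.to_numpy(dtype=float))
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
        raise ValueError(f"{path}: non-finite time_s at row {row}")
    if (times < 0).any():
        row = int(np.flatnonzero((times < 0).to_numpy())[0]) + 2
        raise ValueError(f"{path}: negative time_s at row {row}")
    trains = [
        SpikeTrain(uid, np.sort(grp.to_numpy(dtype=float)))
        for uid, grp in times.groupby(df["unit_id"], sort=True)
    ]
    dur = float(times.max()) if duration is None else float(duration)
    return Recording(tuple(trains), duration=dur, source=str(path))


def write_raster_csv(rec: Recording, path: str | Path, precision: int = 9) -> None:
    """Write a Recording back to the long CSV format (round-trip safe)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("unit_id,time_s\n")
        for train in rec.trains:
            for t in train.times:
                fh.write(f"{train.unit_id},{t:.{precision}f}\n")


def apply_cleaning(rec: Recording, spec: CleaningSpec) -> Recording:
    """Drop excluded-window events and removed units; keep the clock.

    Idempotent: applying the same spec twice equals applying it once.
    """
    present = set(rec.unit_ids)
    for uid in spec.removed_units:
        if uid not in present:
            warnings.warn(f"removed_unit {uid!r} not present in recording")
    kept = []
    for train in rec.trains:
        if train.unit_id in spec.removed_units:
            continue
        mask = np.ones(len(train), dtype=bool)
        for start, end in spec.excluded_windows:
            mask &= ~((train.times >= start) & (train.times < end))
        kept.append(SpikeTrain(train.unit_id, train.times[mask]))
    if not kept or all(len(t) == 0 for t in kept):
        raise ValueError("empty recording after cleaning")
    return Recording(tuple(kept), rec.duration, rec.treatments, rec.source)


def active_unit_mask(
    rec: Recording, window: float = 60.0, min_spikes: int = 10
) -> pd.DataFrame:
    """Per-unit, per-window activity flags.

    A unit is active in window ``k`` (covering ``[k*window, (k+1)*window)``)
    iff it has at least ``min_spikes`` events there.  One minute with a
    10-spike floor is the conventional MEA activity criterion.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n_win = max(1, math.ceil(rec.duration / window))
    edges = np.arange(n_win + 1) * window
    rows = {}
    for train in rec.trains:
        counts, _ = np.histogram(train.times, bins=edges)
        rows[train.unit_id] = counts >= min_spikes
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(n_win))


# --- vendor-format adapter hook -------------------------------------------

_ADAPTERS: dict[str, Callable[[Path], Recording]] = {}


def register_adapter(suffix: str, reader: Callable[[Path], Recording]) -> None:
    """Register a reader for a vendor file suffix (e.g. ``".plx"``).

    The reader takes a path and must return a :class:`Recording`; this lets
    users plug in e.g. a Plexon loader without touching the core.
    """
    _ADAPTERS[suffix.lower()] = reader


def load_recording(path: str | Path, duration: float | None = None) -> Recording:
    """Load a recording, dispatching on suffix (CSV native, adapters else)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in _ADAPTERS:
        return _ADAPTERS[suffix](path)
    return read_raster_csv(path, duration=duration)
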