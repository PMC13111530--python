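"""Categorical classification of shape metrics and their dynamics.

Each non-sparse correlogram gets three labels — uniformity, peak-count
class, and leader/follower strength — plus a multiset of peak-time labels
(timescale decades or EEG-style frequency bands).  Region-resolved label
fractions, region-to-region (or period-pooled) transition probabilities,
and the combined uniformity x strength x peak-count combo table summarize
how firing dynamics evolve across a recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import PeriodAssignment

__all__ = [
    "ClassificationRecord",
    "TransitionTable",
    "LF_CLASSES",
    "FREQUENCY_BANDS",
    "classify_uniformity",
    "classify_peak_count",
    "classify_peak_times",
    "classify_leader_follower",
    "classify_records",
    "class_fractions",
    "transition_probabilities",
    "combined_combo_table",
]

#: leader/follower strength classes, weakest to strongest
LF_CLASSES = ("weak", "fairly_weak", "intermediate", "fairly_strong", "strong")

#: contiguous half-open frequency bands in Hz (EEG naming convention)
FREQUENCY_BANDS = (
    ("delta", 0.0, 4.0),
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("beta", 13.0, 32.0),
    ("gamma", 32.0, math.inf),
)


@dataclass(frozen=True)
class ClassificationRecord:
    """The categorical labels of one correlogram in one region."""

    region_index: int
    ref_id: str
    cmp_id: str
    uniformity_class: str        # "uniform" | "nonuniform"
    peak_class: str              # "0", "1", ..., "M+"
    lf_class: str                # one of LF_CLASSES
    peak_time_classes: tuple     # multiset of timescale/band labels

    @property
    def is_auto(self) -> bool:
        return self.ref_id == self.cmp_id


@dataclass(frozen=True)
class TransitionTable:
    """Row-stochastic class-transition matrix for one grouping.

    ``matrix`` rows are source classes, columns destination classes; each
    row with nonzero ``support`` sums to 1.  ``skipped`` counts steps
    dropped because either endpoint was sparse.
    """

    grouping: str
    matrix: pd.DataFrame
    support: pd.Series
    skipped: int = 0


def classify_uniformity(p_value: float, alpha: float = 0.05) -> str:
    """"uniform" iff p > alpha; p exactly at alpha counts as nonuniform."""
    if not 0 <= p_value <= 1:
        raise ValueError("p-value outside [0, 1]")
    return "uniform" if p_value > alpha else "nonuniform"


def classify_peak_count(count: int, max_class: int = 4) -> str:
    """Peak-count class: "0".."M-1" or the ceiling class "M+"."""
    if count < 0 or max_class < 1:
        raise ValueError("count >= 0 and max_class >= 1 required")
    return str(count) if count < max_class else f"{max_class}+"


def peak_count_classes(max_class: int) -> list[str]:
    return [str(k) for k in range(max_class)] + [f"{max_class}+"]


def timescale_classes(range_s: float) -> list[tuple[str, float, float]]:
    """Log-decade |t| classes anchored at the correlogram range.

    For R = 1 s: |t| <= 1 ms, (1, 10] ms, (10, 100] ms, (100 ms, 1 s] —
    i.e. one class per decade plus the sub-floor class.
    """
    n_decades = int(round(math.log10(range_s / 0.001)))
    n_decades = max(n_decades, 0)
    uppers = [range_s / 10**k for k in range(n_decades + 1)][::-1]
    out = []
    lo = 0.0
    for up in uppers:
        label = f"<= {up:g} s" if lo == 0 else f"({lo:g}, {up:g}] s"
        out.append((label, lo, up))
        lo = up
    return out


def classify_peak_times(
    times, mode: str = "timescale", range_s: float = 1.0
) -> tuple:
    """Label each peak lag by timescale decade or frequency band.

    Timescale mode sorts ``|t|`` into log-decade classes anchored at the
    range (half-open on the left, closed on the right; |t| = 0 falls in
    the smallest class).  Frequency mode maps ``f = 1/|t|`` into the
    contiguous bands delta [0,4), theta [4,8), alpha [8,13), beta [13,32),
    gamma [32,inf) Hz; lag 0 has undefined f and is skipped.
    """
    labels = []
    if mode == "timescale":
        classes = timescale_classes(range_s)
        for t in times:
            a = abs(t)
            for label, lo, up in classes:
                if (a <= up and a > lo) or (lo == 0.0 and a <= up):
                    labels.append(label)
                    break
    elif mode == "frequency":
        for t in times:
            a = abs(t)
            if a == 0:
                continue  # f = 1/|t| undefined at lag 0
            f = 1.0 / a
            for label, lo, up in FREQUENCY_BANDS:
                if lo <= f < up:
                    labels.append(label)
                    break
    else:
        raise ValueError(f"unknown peak-time mode {mode!r}")
    return tuple(labels)


def classify_leader_follower(A: float) -> str:
    """Five-way leader/follower strength from area left of zero.

    weak 0.4<A<0.6; fairly_weak 0.6<=A<0.7 or 0.3<A<=0.4; intermediate
    0.7<=A<0.8 or 0.2<A<=0.3; fairly_strong 0.8<=A<0.9 or 0.1<A<=0.2;
    strong A>=0.9 or A<=0.1.  Mirror-consistent: A and 1-A share a class.
    """
    if not 0 <= A <= 1:
        raise ValueError("A outside [0, 1]")
    # snap to a class boundary when within float noise of it, so that the
    # mirrored value 1-A always lands in the same class
    tenths = round(A * 10)
    if abs(A * 10 - tenths) < 1e-9:
        A = tenths / 10
    # direct interval tests on A (not |A-0.5|) keep boundaries float-exact
    if 0.4 < A < 0.6:
        return "weak"
    if 0.6 <= A < 0.7 or 0.3 < A <= 0.4:
        return "fairly_weak"
    if 0.7 <= A < 0.8 or 0.2 < A <= 0.3:
        return "intermediate"
    if 0.8 <= A < 0.9 or 0.1 < A <= 0.2:
        return "fairly_strong"
    return "strong"


def classify_records(
    metrics_rows,
    alpha: float = 0.05,
    max_peak_class: int = 4,
    peak_time_mode: str = "timescale",
    range_s: float = 1.0,
) -> list[ClassificationRecord]:
    """Classify (region, ref, cmp, ShapeMetrics) tuples; sparse rows skipped."""
    records = []
    for region_index, ref_id, cmp_id, sm in metrics_rows:
        if sm is None:
            continue
        records.append(
            ClassificationRecord(
                region_index=region_index,
                ref_id=ref_id,
                cmp_id=cmp_id,
                uniformity_class=classify_uniformity(sm.p_value, alpha),
                peak_class=classify_peak_count(sm.peak_count, max_peak_class),
                lf_class=classify_leader_follower(sm.area_left),
                peak_time_classes=classify_peak_times(
                    sm.peak_times, peak_time_mode, range_s
                ),
            )
        )
    return records


_SCHEMES = ("uniformity_class", "peak_class", "lf_class")


def _filtered(records, include_autocorrelograms):
    return [
        r for r in records if include_autocorrelograms or not r.is_auto
    ]


def class_fractions(
    records, include_autocorrelograms: bool = False
) -> pd.DataFrame:
    """Per-region fraction of correlograms in each class, per scheme.

    Fractions within one (region, scheme) sum to 1.  Autocorrelograms are
    excluded by default to focus on between-cell interactions.
    """
    rows = []
    recs = _filtered(records, include_autocorrelograms)
    by_region: dict[int, list] = {}
    for r in recs:
        by_region.setdefault(r.region_index, []).append(r)
    for region_index in sorted(by_region):
        group = by_region[region_index]
        for scheme in _SCHEMES:
            values = [getattr(r, scheme) for r in group]
            n = len(values)
            for cls in sorted(set(values)):
                rows.append(
                    {
                        "region_index": region_index,
                        "scheme": scheme,
                        "class": cls,
                        "fraction": values.count(cls) / n,
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


def transition_probabilities(
    records,
    scheme: str = "uniformity_class",
    step: str = "region",
    periods: PeriodAssignment | None = None,
    include_autocorrelograms: bool = False,
) -> list[TransitionTable]:
    """Class-transition probabilities between consecutive regions.

    For each consecutive region pair (r-1, r) and each correlogram
    identity, the step class(r-1) -> class(r) is tallied; rows are
    normalized to conditional probabilities.  ``step="region"`` emits one
    table per consecutive pair; ``step="period"`` pools steps by the
    period of the destination region (so the step crossing a treatment
    belongs to "after").  Steps with a sparse endpoint are skipped and
    counted.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    recs = _filtered(records, include_autocorrelograms)
    by_key = {(r.region_index, r.ref_id, r.cmp_id): getattr(r, scheme) for r in recs}
    observed = sorted({r.region_index for r in recs})
    # step over every consecutive region in range; a region with no
    # (non-sparse) record for an identity contributes a skipped step
    region_indices = list(range(observed[0], observed[-1] + 1)) if observed else []
    identities = sorted({(r.ref_id, r.cmp_id) for r in recs})
    classes = sorted({getattr(r, scheme) for r in recs})

    steps: dict[str, list[tuple[str, str]]] = {}
    skipped: dict[str, int] = {}
    for prev, cur in zip(region_indices, region_indices[1:]):
        if step == "region":
            label = f"{prev}->{cur}"
        elif step == "period":
            if periods is None:
                raise ValueError("period pooling needs a PeriodAssignment")
            label = periods.period_of(cur)
        else:
            raise ValueError(f"unknown step mode {step!r}")
        steps.setdefault(label, [])
        skipped.setdefault(label, 0)
        for ident in identities:
            src = by_key.get((prev, *ident))
            dst = by_key.get((cur, *ident))
            if src is None or dst is None:
                skipped[label] += 1
                continue
            steps[label].append((src, dst))

    tables = []
    for label, pairs in steps.items():
        mat = pd.DataFrame(0.0, index=classes, columns=classes)
        support = pd.Series(0, index=classes, dtype=int)
        for src, dst in pairs:
            mat.loc[src, dst] += 1
            support[src] += 1
        for cls in classes:
            if support[cls] > 0:
                mat.loc[cls] /= support[cls]
        tables.append(
            TransitionTable(label, mat, support, skipped=skipped[label])
        )
    return tables


def combined_combo_table(
    records,
    max_peak_class: int = 4,
    grouping: dict | None = None,
    include_autocorrelograms: bool = False,
) -> pd.DataFrame:
    """Percent of correlograms per (uniformity, lf, peak-count) combo.

    The full cell set has 2 * 5 * (M+1) combinations (110 at M=10); cells
    within one grouping sum to 100%.  ``grouping`` maps region index to a
    group label (e.g. a PeriodAssignment mapping); default is one global
    group "all".
    """
    recs = _filtered(records, include_autocorrelograms)
    peak_classes = peak_count_classes(max_peak_class)
    index = pd.MultiIndex.from_product(
        [("uniform", "nonuniform"), LF_CLASSES, peak_classes],
        names=["uniformity_class", "lf_class", "peak_class"],
    )
    groups: dict[str, list] = {}
    for r in recs:
        label = grouping.get(r.region_index, "all") if grouping else "all"
        groups.setdefault(label, []).append(r)
    columns = sorted(groups) or ["all"]
    cell_pos = {key: i for i, key in enumerate(index)}
    arr = np.zeros((len(index), len(columns)))
    for j, label in enumerate(columns):
        group = groups.get(label, [])
        for r in group:
            arr[cell_pos[(r.uniformity_class, r.lf_class, r.peak_class)], j] += 1
        if group:
            arr[:, j] *= 100.0 / len(group)
    return pd.DataFrame(arr, index=index, columns=columns)
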