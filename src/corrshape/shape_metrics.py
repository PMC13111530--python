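"""Correlogram shape metrics: uniformity, peaks, and area left of zero.

Three metrics summarize each correlogram's shape:

* **Uniformity** — a chi-squared goodness-of-fit test of the bin counts
  against the flat distribution ``C(x) = 1/L``.  A flat correlogram means
  the two signals fire independently.
* **Peak count and peak times** — local maxima of the (optionally
  loess-smoothed) probability correlogram whose prominence strictly
  exceeds ``1/L``, i.e. peaks that stand out more than the wiggles of a
  uniform distribution.  More peaks indicate more diverse firing patterns.
* **Area left of zero (A)** — the probability mass at negative lags,
  quantifying how consistently the comparison signal fires before the
  reference (leader/follower strength).  The center-bin mass is split
  half/half so that the mirror identity ``A(j,i) = 1 - A(i,j)`` holds
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .correlogram import Correlogram, is_sparse

__all__ = [
    "MetricParams",
    "ShapeMetrics",
    "chi_squared_uniformity",
    "smooth_correlogram",
    "find_peaks",
    "count_and_time_peaks",
    "area_left_of_zero",
    "compute_metrics",
]

#: below this expected count per bin the chi-squared approximation is shaky
EXPECTED_COUNT_FLOOR = 5.0


@dataclass(frozen=True)
class MetricParams:
    """Tunable knobs for shape quantification.

    alpha
        Significance cutoff: a correlogram is *uniform* iff p > alpha.
    smooth_window
        Odd loess window W in bins applied before peak finding; 1 disables
        smoothing.
    min_prominence
        Prominence floor for peaks; ``None`` means the uniform-level 1/L.
    chi2_variant
        "pearson" (default): chi2 = sum (O-E)^2 / E, the statistic the
        chi-squared(L-1) tail is valid for.  "as_printed": sum (O-E)^2,
        for comparison against outputs computing the statistic that way.
    half_center
        Split the lag-0 bin's mass equally between the two sides of A.
        Disabling it excludes the center bin from A entirely.
    """

    alpha: float = 0.05
    smooth_window: int = 5
    min_prominence: float | None = None
    chi2_variant: str = "pearson"
    half_center: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be an odd integer >= 1")
        if self.chi2_variant not in ("pearson", "as_printed"):
            raise ValueError(f"unknown chi2_variant {self.chi2_variant!r}")


@dataclass(frozen=True)
class ShapeMetrics:
    """Shape metrics of one correlogram (absent for sparse input)."""

    chi2: float
    p_value: float
    uniform: bool
    peak_count: int
    peak_times: tuple
    area_left: float
    expected_count_warning: bool


def chi_squared_uniformity(
    cg: Correlogram, params: MetricParams = MetricParams()
) -> tuple[float, float, bool]:
    """Test a correlogram's bin counts against the uniform distribution.

    Observed counts O_x (= S*C(x)) are compared with the flat expectation
    E = S/L; the p-value is the upper tail of chi-squared with L-1 degrees
    of freedom.  Uniform iff p > alpha (p exactly at alpha is nonuniform).
    """
    counts = np.asarray(cg.counts, dtype=float)
    L = counts.size
    S = counts.sum()
    if S == 0:
        raise ValueError("empty correlogram: uniformity undefined")
    if L < 2:
        raise ValueError("need at least 2 bins")
    expected = S / L
    resid_sq = (counts - expected) ** 2
    if params.chi2_variant == "pearson":
        chi2 = float(resid_sq.sum() / expected)
    else:  # literal sum of squared deviations, no /E
        chi2 = float(resid_sq.sum())
    p = float(stats.chi2.sf(chi2, L - 1))
    return chi2, p, p > params.alpha


def smooth_correlogram(probs: np.ndarray, window: int) -> np.ndarray:
    """Loess-style local quadratic smoothing with tricube weights.

    Each bin is replaced by the value at that bin of a weighted quadratic
    regression over a centered window of ``window`` bins; at the edges the
    window is truncated to the available bins.  ``window=1`` is a no-op.
    Exactly quadratic input is reproduced wherever the window is not
    truncated.
    """
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    probs = np.asarray(probs, dtype=float)
    L = probs.size
    if window == 1 or L < 3:
        return probs.copy()
    h = min((window - 1) // 2, L - 1)

    def fit_at(center: int) -> float:
        lo, hi = max(0, center - h), min(L - 1, center + h)
        d = np.arange(lo, hi + 1) - center
        dmax = np.abs(d).max()
        w = (1 - (np.abs(d) / dmax) ** 3) ** 3 if dmax > 0 else np.ones_like(d, float)
        pos = w > 0
        if pos.sum() < 3:
            return probs[center]
        X = np.column_stack([np.ones(d.size), d, d * d])
        sw = np.sqrt(w[pos])
        coef, *_ = np.linalg.lstsq(X[pos] * sw[:, None], probs[lo : hi + 1][pos] * sw, rcond=None)
        return float(coef[0])

    out = np.empty(L)
    # interior bins share one full window -> the fit is a fixed convolution
    if L >= 2 * h + 1:
        d = np.arange(-h, h + 1)
        dmax = max(h, 1)
        w = (1 - (np.abs(d) / dmax) ** 3) ** 3
        pos = w > 0
        if pos.sum() >= 3:
            X = np.column_stack([np.ones(d.size), d, d * d])
            Xw = X[pos] * w[pos][:, None]
            # row of the hat matrix for the window center
            kernel_pos = np.linalg.solve(X[pos].T @ Xw, Xw.T)[0]
            kernel = np.zeros(d.size)
            kernel[pos] = kernel_pos
            out[h : L - h] = np.convolve(probs, kernel[::-1], mode="valid")
        else:
            out[h : L - h] = probs[h : L - h]
        edge_idx = list(range(h)) + list(range(L - h, L))
    else:
        edge_idx = list(range(L))
    for i in edge_idx:
        out[i] = fit_at(i)
    return out


def find_peaks(
    smoothed: np.ndarray, min_prominence: float
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and prominences of peaks strictly exceeding the floor.

    A peak is a strict local maximum (plateaus collapse to their middle
    bin; endpoints are never peaks).  Prominence is the height above the
    higher of the two flanking reference minima, each taken between the
    peak and its nearest higher value (or the signal end) on that side.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.size < 3:
        raise ValueError("need at least 3 bins for peak detection")
    idx, _ = signal.find_peaks(smoothed)
    if idx.size == 0:
        return idx, np.empty(0)
    prom = signal.peak_prominences(smoothed, idx)[0]
    keep = prom > min_prominence
    return idx[keep], prom[keep]


def count_and_time_peaks(
    cg: Correlogram, params: MetricParams = MetricParams()
) -> tuple[int, np.ndarray]:
    """Peak count and signed peak lags (seconds) of a correlogram."""
    probs = cg.probs
    if probs is None:
        raise ValueError("empty correlogram: peaks undefined")
    floor = (
        params.min_prominence
        if params.min_prominence is not None
        else 1.0 / cg.n_bins
    )
    smoothed = smooth_correlogram(probs, params.smooth_window)
    idx, _ = find_peaks(smoothed, floor)
    return int(idx.size), cg.bin_centers[idx]


def area_left_of_zero(cg: Correlogram, half_center: bool = True) -> float:
    """A: probability mass at negative lags.

    With ``half_center`` (default) half of the lag-0 bin's mass counts as
    left, making ``A(j,i) = 1 - A(i,j)`` exact; without it the center bin
    is excluded entirely.
    """
    probs = cg.probs
    if probs is None:
        raise ValueError("empty correlogram: area undefined")
    center = cg.n_bins // 2
    A = float(probs[:center].sum())
    if half_center:
        A += 0.5 * float(probs[center])
    return A


def compute_metrics(
    cg: Correlogram,
    params: MetricParams = MetricParams(),
    sparsity_threshold: int = 0,
) -> ShapeMetrics | None:
    """All three shape metrics for one correlogram; None when sparse."""
    if is_sparse(cg, sparsity_threshold):
        return None
    chi2, p, uniform = chi_squared_uniformity(cg, params)
    n_peaks, peak_times = count_and_time_peaks(cg, params)
    A = area_left_of_zero(cg, params.half_center)
    warn = (cg.total / cg.n_bins) < EXPECTED_COUNT_FLOOR
    return ShapeMetrics(
        chi2=chi2,
        p_value=p,
        uniform=uniform,
        peak_count=n_peaks,
        peak_times=tuple(float(t) for t in peak_times),
        area_left=A,
        expected_count_warning=warn,
    )
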