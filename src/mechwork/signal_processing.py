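"""Filtering, differentiation and extrema detection shared by all stages.

The joint-angle/kinematic streams this package consumes are smoothed with
a zero-lag Butterworth low-pass filter.  Biomechanics convention is
ambiguous about whether the quoted filter order refers to the designed
order or to the effective order after the forward-backward pass; both
interpretations are supported through ``convention`` ("effective",
the default, designs order/2 per pass; "per-pass" designs the full
order each way).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

__all__ = [
    "TimeSeries",
    "butterworth_lowpass",
    "residual_analysis_cutoff",
    "differentiate",
    "find_local_extrema",
    "Extrema",
]


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled series: scalar ``(n,)`` or vector ``(n, 3)``."""

    values: np.ndarray
    rate: float  # Hz

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.values.ndim not in (1, 2):
            raise ValueError(f"values must be 1-D or 2-D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite samples; resolve gaps upstream")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self)) / self.rate


def butterworth_lowpass(
    series: TimeSeries,
    cutoff: float,
    order: int = 4,
    convention: str = "effective",
) -> TimeSeries:
    """Zero-lag (forward-backward) Butterworth low-pass filter.

    With ``convention="effective"`` the quoted ``order`` is the effective
    order after the bidirectional pass, so a filter of half that order is
    designed and applied each way (order must then be even).  Edges are
    handled by reflecting up to one second of signal.
    """
    if not 0 < cutoff < series.nyquist:
        raise ValueError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={series.nyquist} Hz)"
        )
    if convention == "effective":
        if order % 2:
            raise ValueError(f"effective order must be even, got {order}")
        design_order = order // 2
    elif convention == "per-pass":
        design_order = order
    else:
        raise ValueError(f"unknown order convention {convention!r}")
    sos = _sig.butter(design_order, cutoff, btype="low", fs=series.rate, output="sos")
    n = len(series)
    padlen = min(int(round(series.rate)), n - 2)
    filtered = _sig.sosfiltfilt(sos, series.values, axis=0, padtype="even", padlen=max(padlen, 0))
    return TimeSeries(values=filtered, rate=series.rate)


def residual_analysis_cutoff(
    series: TimeSeries,
    candidate_cutoffs: np.ndarray | list[float],
    order: int = 4,
    convention: str = "effective",
) -> float:
    """Select a low-pass cutoff by Winter-style residual analysis.

    The RMS residual between the raw and filtered signal is computed for
    each candidate cutoff; a straight line is fitted to the residuals of
    the noise-dominated upper half of the candidate range and
    extrapolated to 0 Hz to estimate the noise floor.  The selected
    cutoff is the smallest candidate whose residual does not exceed that
    noise estimate.
    """
    candidates = np.asarray(candidate_cutoffs, dtype=float)
    if candidates.size < 4:
        raise ValueError(f"need at least 4 candidate cutoffs, got {candidates.size}")
    if np.any(np.diff(candidates) <= 0):
        raise ValueError("candidate cutoffs must be strictly ascending")
    if candidates[0] <= 0 or candidates[-1] >= series.nyquist:
        raise ValueError("candidates must lie strictly inside (0, Nyquist)")
    residuals = np.empty_like(candidates)
    for i, fc in enumerate(candidates):
        filtered = butterworth_lowpass(series, fc, order=order, convention=convention)
        residuals[i] = float(np.sqrt(np.mean((series.values - filtered.values) ** 2)))
    tail = candidates.size // 2
    slope, intercept = np.polyfit(candidates[tail:], residuals[tail:], 1)
    # Tiny slack keeps the noiseless case (all-residuals ~ 0) well defined.
    threshold = intercept + 1e-9 * max(residuals.max(), 1.0) + 1e-12
    below = np.nonzero(residuals <= threshold)[0]
    if below.size == 0:
        return float(candidates[-1])
    return float(candidates[below[0]])


def differentiate(series: TimeSeries) -> TimeSeries:
    """Time derivative: central differences inside, one-sided at the ends.

    The one-sided end stencils are second order, so the derivative is
    exact for quadratic signals (ballistic trajectories differentiate to
    machine precision).
    """
    if len(series) < 3:
        raise ValueError(f"need at least 3 samples to differentiate, got {len(series)}")
    deriv = np.gradient(series.values, 1.0 / series.rate, axis=0, edge_order=2)
    return TimeSeries(values=deriv, rate=series.rate)


@dataclass(frozen=True)
class Extrema:
    """Strict interior extrema of a scalar series.

    Plateaus are resolved to their first sample.  Prominences follow the
    topographic convention (height above the higher of the two bounding
    saddles).
    """

    minima: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    maxima: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    min_prominences: np.ndarray = field(default_factory=lambda: np.array([]))
    max_prominences: np.ndarray = field(default_factory=lambda: np.array([]))

    def most_prominent_maximum(self) -> int:
        """Index of the most prominent maximum; ties go to the earliest."""
        if self.maxima.size == 0:
            raise ValueError("series has no interior maxima")
        best = np.nonzero(self.max_prominences == self.max_prominences.max())[0][0]
        return int(self.maxima[best])


def _peaks(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    idx, props = _sig.find_peaks(x, prominence=0.0, plateau_size=1)
    # Plateau peaks are reported at their centre; move to the first index.
    return props["left_edges"].astype(int), props["prominences"]


def find_local_extrema(series: TimeSeries) -> Extrema:
    """Locate strict interior minima and maxima with their prominences."""
    if len(series) < 3:
        raise ValueError(f"need at least 3 samples, got {len(series)}")
    x = np.asarray(series.values, dtype=float)
    if x.ndim != 1:
        raise ValueError("extrema detection expects a scalar series")
    maxima, max_prom = _peaks(x)
    minima, min_prom = _peaks(-x)
    return Extrema(
        minima=minima,
        maxima=maxima,
        min_prominences=min_prom,
        max_prominences=max_prom,
    )
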