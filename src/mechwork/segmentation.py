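"""Trial cropping, protocol event detection and the fatigue measure.

Each captured trial contains one set of the protocol (serve + eight
alternating groundstrokes) followed by a maximal sprint to the net.  The
analysed window runs from the start of the serve (second local minimum
of CoM height before the most prominent vertical peak — the top of the
serve) to the sample at which the CoM has travelled 8.5 m forward of the
baseline, split at the change of direction into the sprint (last
prominent local minimum of resultant CoM speed before the rise to the
sprint's peak speed).  Peak forward CoM velocity during the sprint
window is the per-cycle fatigue measure.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .signal_processing import TimeSeries, find_local_extrema

__all__ = [
    "TrialBoundaries",
    "CycleRecord",
    "PlayerSeries",
    "SegmentationError",
    "detect_serve_start",
    "detect_sprint_end",
    "detect_transition",
    "peak_forward_velocity",
    "build_player_series",
    "WORK_VARIANTS",
]

#: Work variants tracked through the fatigue analysis (positive work).
WORK_VARIANTS = ("total", "external", "pelvis", "bounding_box")

_VARIANT_FIELDS = {
    "total": "w_tot_pos",
    "external": "w_ext_pos",
    "pelvis": "w_pelvis_pos",
    "bounding_box": "w_bb_pos",
}


class SegmentationError(RuntimeError):
    """A protocol event could not be located in a trial."""


@dataclass(frozen=True)
class TrialBoundaries:
    """Sample indices delimiting the analysed window of a trial."""

    start: int
    transition: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.transition < self.end:
            raise ValueError(
                f"boundaries must be ordered start < transition < end, got "
                f"{self.start}, {self.transition}, {self.end}"
            )


@dataclass(frozen=True)
class CycleRecord:
    """Per-cycle fatigue and workload record for one player."""

    cycle_index: int
    peak_velocity: float  # m/s
    peak_velocity_pct: float  # % of the player's overall maximum
    cumulative_work: Mapping[str, float | None]  # J/kg per work variant

    def __post_init__(self) -> None:
        if self.cycle_index < 1:
            raise ValueError(f"cycle_index must be >= 1, got {self.cycle_index}")
        if not 0.0 < self.peak_velocity_pct <= 100.0 + 1e-9:
            raise ValueError(
                f"peak_velocity_pct={self.peak_velocity_pct} outside (0, 100]"
            )


@dataclass(frozen=True)
class PlayerSeries:
    """Ordered per-cycle records for one player."""

    player_id: str
    baseline_peak: float
    records: tuple[CycleRecord, ...] = field(default_factory=tuple)

    @property
    def n_cycles(self) -> int:
        return len(self.records)


def detect_serve_start(
    vertical_com: TimeSeries,
    min_prominence: float = 0.01,
) -> int:
    """Serve start: second local minimum before the top of the serve.

    The top of the serve is the most prominent peak of the vertical CoM
    series; the start index is the second local minimum counting
    strictly backwards from it.  ``min_prominence`` (m) screens out
    noise-scale wiggles when ranking extrema.
    """
    extrema = find_local_extrema(vertical_com)
    keep = extrema.max_prominences >= min_prominence
    maxima = extrema.maxima[keep]
    max_prom = extrema.max_prominences[keep]
    if maxima.size == 0:
        raise SegmentationError("no prominent vertical CoM peak found (no serve?)")
    peak = int(maxima[np.nonzero(max_prom == max_prom.max())[0][0]])
    minima = extrema.minima[extrema.min_prominences >= min_prominence]
    prior = minima[minima < peak]
    if prior.size < 2:
        raise SegmentationError(
            f"only {prior.size} local minima precede the serve peak at sample "
            f"{peak}; need two to locate the serve start"
        )
    return int(prior[-2])


def detect_sprint_end(forward_position: TimeSeries, threshold: float = 8.5) -> int:
    """First sample at which the CoM is ``threshold`` m forward of the baseline."""
    values = np.asarray(forward_position.values)
    if values.ndim != 1:
        raise ValueError("forward_position must be a scalar series")
    reached = values >= threshold
    if not reached.any():
        raise SegmentationError(
            f"incomplete sprint: forward position never reached {threshold} m "
            f"(max {values.max():.3f} m)"
        )
    return int(np.argmax(reached))


def detect_transition(
    resultant_velocity: TimeSeries,
    search_from: int,
    min_prominence: float = 0.3,
) -> int:
    """Change of direction from the last groundstroke into the sprint.

    The last prominent local minimum of resultant CoM speed before the
    rise to the sprint's peak speed.  ``min_prominence`` (m/s) ignores
    noise-scale speed ripples.
    """
    speed = np.asarray(resultant_velocity.values)
    if speed.ndim != 1:
        raise ValueError("resultant_velocity must be a scalar series")
    if not 0 <= search_from < speed.shape[0] - 2:
        raise SegmentationError(f"search_from={search_from} leaves no search window")
    window = TimeSeries(speed[search_from:], resultant_velocity.rate)
    extrema = find_local_extrema(window)
    peak = int(np.argmax(window.values))
    keep = (extrema.min_prominences >= min_prominence) & (extrema.minima < peak)
    candidates = extrema.minima[keep]
    if candidates.size == 0:
        raise SegmentationError(
            "no prominent local minimum of CoM speed before the sprint peak"
        )
    return search_from + int(candidates[-1])


def peak_forward_velocity(
    com_velocity_forward: TimeSeries,
    boundaries: TrialBoundaries,
) -> float:
    """Maximum forward CoM velocity over the sprint window (m/s)."""
    values = np.asarray(com_velocity_forward.values)
    return float(values[boundaries.transition : boundaries.end + 1].max())


def build_player_series(
    cycle_results: Sequence[tuple[float, Mapping[str, float | None]]],
    baseline_peak: float,
    player_id: str = "P00",
) -> PlayerSeries:
    """Assemble per-cycle records from processed trials.

    ``cycle_results`` is the protocol-ordered list of
    ``(peak_velocity, per_cycle_positive_work)`` pairs, one per completed
    cycle, where the work mapping holds the per-cycle positive work per
    variant (``None`` for absent proxies).  Peak velocities are expressed
    as a percentage of the player's overall maximum (the larger of the
    baseline and any cycle peak); work accumulates across cycles.
    """
    if not cycle_results:
        raise ValueError("cycle_results is empty")
    peaks = [peak for peak, _ in cycle_results]
    overall_max = max([baseline_peak, *peaks])
    cumulative: dict[str, float | None] = {variant: 0.0 for variant in WORK_VARIANTS}
    records = []
    for index, (peak, work) in enumerate(cycle_results, start=1):
        for variant in WORK_VARIANTS:
            value = work.get(variant)
            if value is None:
                cumulative[variant] = None
            elif cumulative[variant] is not None:
                cumulative[variant] = cumulative[variant] + float(value)
        records.append(
            CycleRecord(
                cycle_index=index,
                peak_velocity=float(peak),
                peak_velocity_pct=100.0 * float(peak) / overall_max,
                cumulative_work=dict(cumulative),
            )
        )
    return PlayerSeries(player_id=player_id, baseline_peak=float(baseline_peak),
                        records=tuple(records))


def work_variant_value(summary, variant: str) -> float | None:
    """Positive work of ``variant`` from a WorkSummary."""
    return getattr(summary, _VARIANT_FIELDS[variant])
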