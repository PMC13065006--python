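"""Centre-of-mass and limb mechanical energies, and work bookkeeping.

Mechanical work follows the classical external/internal decomposition of
whole-body energetics: external work is the sum of increments (positive
work) and decrements (negative work) of the CoM kinetic + potential
energy series; internal work is the corresponding bookkeeping applied to
segment kinetic energies expressed relative to the CoM, summed within
limbs (bilateral legs, bilateral arms, trunk) before increments are
taken, then summed across limbs.  All energies and work are
mass-normalised (J/kg); multiply by subject mass for absolute Joules.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .body_model import LIMB_GROUPS, ScaledSegment
from .signal_processing import TimeSeries, differentiate

__all__ = [
    "GRAVITY",
    "EnergySeries",
    "WorkSummary",
    "com_energy",
    "limb_energies",
    "positive_negative_work",
    "cycle_work",
    "trial_work",
]

GRAVITY = 9.81  # m/s^2

_WORK_FIELDS = (
    "w_ext_pos", "w_ext_neg",
    "w_int_pos", "w_int_neg",
    "w_tot_pos", "w_tot_neg",
    "w_pelvis_pos", "w_pelvis_neg",
    "w_bb_pos", "w_bb_neg",
)


@dataclass(frozen=True)
class EnergySeries:
    """Kinetic, potential and total mechanical energy per sample (J/kg)."""

    ke: np.ndarray
    pe: np.ndarray
    total: np.ndarray
    rate: float
    subject_mass: float

    def __post_init__(self) -> None:
        for name in ("ke", "pe", "total"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.ke.shape != self.pe.shape or self.ke.shape != self.total.shape:
            raise ValueError("ke, pe and total must have identical shapes")
        if np.any(self.ke < -1e-12):
            raise ValueError("kinetic energy must be non-negative")
        if np.max(np.abs(self.total - (self.ke + self.pe)), initial=0.0) > 1e-9:
            raise ValueError("total energy must equal ke + pe")

    def __len__(self) -> int:
        return self.ke.shape[0]


@dataclass(frozen=True)
class WorkSummary:
    """Positive/negative work over one trial section (J/kg).

    Proxy fields are ``None`` when the corresponding trajectory was
    absent from the trial (explicitly flagged, never silently zero).
    """

    section: str  # {"groundstrokes", "sprint", "cycle"}
    w_ext_pos: float
    w_ext_neg: float
    w_int_pos: float
    w_int_neg: float
    w_tot_pos: float
    w_tot_neg: float
    w_pelvis_pos: float | None = None
    w_pelvis_neg: float | None = None
    w_bb_pos: float | None = None
    w_bb_neg: float | None = None

    def __post_init__(self) -> None:
        if self.section not in ("groundstrokes", "sprint", "cycle"):
            raise ValueError(f"unknown section {self.section!r}")
        for name in _WORK_FIELDS:
            value = getattr(self, name)
            if value is None:
                continue
            if name.endswith("_pos") and value < -1e-12:
                raise ValueError(f"{name}={value} must be non-negative")
            if name.endswith("_neg") and value > 1e-12:
                raise ValueError(f"{name}={value} must be non-positive")
        for sign in ("pos", "neg"):
            tot = getattr(self, f"w_tot_{sign}")
            ext = getattr(self, f"w_ext_{sign}")
            wint = getattr(self, f"w_int_{sign}")
            if abs(tot - (ext + wint)) > 1e-9:
                raise ValueError(
                    f"w_tot_{sign}={tot} must equal w_ext_{sign} + w_int_{sign}"
                )

    def as_dict(self) -> dict[str, float | None]:
        out: dict[str, float | None] = {"section": self.section}  # type: ignore[dict-item]
        out.update({name: getattr(self, name) for name in _WORK_FIELDS})
        return out


def com_energy(
    position: TimeSeries,
    subject_mass: float,
    g: float = GRAVITY,
) -> EnergySeries:
    """Mass-normalised CoM (or proxy point) mechanical energy.

    ``ke = |v|^2 / 2`` with the velocity from :func:`differentiate`;
    ``pe = g * h`` with height taken relative to the first sample, so the
    potential-energy datum is arbitrary (work is invariant to it).
    """
    if g <= 0:
        raise ValueError(f"g must be positive, got {g}")
    values = np.asarray(position.values, dtype=float)
    if values.ndim != 2 or values.shape[1] != 3:
        raise ValueError(f"position must be (n, 3), got {values.shape}")
    if values.shape[0] < 3:
        raise ValueError("need at least 3 samples for a velocity estimate")
    velocity = differentiate(position).values
    ke = 0.5 * np.einsum("nk,nk->n", velocity, velocity)
    pe = g * (values[:, 2] - values[0, 2])
    return EnergySeries(ke=ke, pe=pe, total=ke + pe, rate=position.rate,
                        subject_mass=subject_mass)


def limb_energies(
    relative_velocities: Mapping[str, np.ndarray],
    angular_velocities: Mapping[str, np.ndarray],
    scaled: Sequence[ScaledSegment],
    rate: float,
    body_mass: float | None = None,
) -> dict[str, EnergySeries]:
    """Per-limb kinetic energy of segment motion relative to the CoM.

    Each segment contributes translational KE ``m |v_rel|^2 / 2`` plus
    rotational KE ``omega . (I omega) / 2`` (principal-axis inertia),
    normalised by total body mass (the summed segment masses unless
    ``body_mass`` is given).  Segment energies are summed within limb
    groups; limb potential energy is identically zero.
    """
    if body_mass is None:
        body_mass = sum(seg.mass for seg in scaled)
    sums: dict[str, np.ndarray | None] = {group: None for group in LIMB_GROUPS}
    for seg in scaled:
        if seg.limb_group not in sums:
            raise ValueError(f"segment {seg.name!r} has unknown limb group {seg.limb_group!r}")
        try:
            v = np.asarray(relative_velocities[seg.name], dtype=float)
            w = np.asarray(angular_velocities[seg.name], dtype=float)
        except KeyError as err:
            raise KeyError(f"missing kinematics for segment {seg.name!r}") from err
        inertia = np.asarray(seg.inertia_principal)
        ke = 0.5 * seg.mass * np.einsum("nk,nk->n", v, v)
        ke = ke + 0.5 * np.einsum("nk,k,nk->n", w, inertia, w)
        ke /= body_mass
        current = sums[seg.limb_group]
        sums[seg.limb_group] = ke if current is None else current + ke
    out: dict[str, EnergySeries] = {}
    for group, ke in sums.items():
        if ke is None:
            continue
        zeros = np.zeros_like(ke)
        out[group] = EnergySeries(ke=ke, pe=zeros, total=ke, rate=rate,
                                  subject_mass=body_mass)
    return out


def positive_negative_work(
    energy: EnergySeries | np.ndarray,
    start: int,
    end: int,
) -> tuple[float, float]:
    """Sum of increments (positive work) and decrements (negative work).

    Over consecutive samples in ``[start, end]`` of the total energy
    series.  The telescoping identity
    ``w_pos + w_neg = E[end] - E[start]`` holds up to floating-point
    summation order.
    """
    total = energy.total if isinstance(energy, EnergySeries) else np.asarray(energy, dtype=float)
    n = total.shape[0]
    if not 0 <= start < end < n:
        raise IndexError(f"invalid index range [{start}, {end}] for series of length {n}")
    deltas = np.diff(total[start : end + 1])
    w_pos = float(np.sum(np.maximum(deltas, 0.0)))
    w_neg = float(np.sum(np.minimum(deltas, 0.0)))
    return w_pos, w_neg


def _combine(a: float | None, b: float | None, factor: float) -> float | None:
    if a is None or b is None:
        return None
    return factor * a + b


def cycle_work(groundstrokes: WorkSummary, sprint: WorkSummary) -> WorkSummary:
    """Per-cycle work: three sets of groundstrokes plus the sprint.

    Only the third set of each cycle is captured; the groundstroke work
    is multiplied by three on the assumption that the three sets of a
    cycle are equivalent.
    """
    if groundstrokes.section != "groundstrokes":
        raise ValueError(f"expected a groundstrokes summary, got {groundstrokes.section!r}")
    if sprint.section != "sprint":
        raise ValueError(f"expected a sprint summary, got {sprint.section!r}")
    fields = {
        name: _combine(getattr(groundstrokes, name), getattr(sprint, name), 3.0)
        for name in _WORK_FIELDS
    }
    return WorkSummary(section="cycle", **fields)  # type: ignore[arg-type]


def _section_work(energy: EnergySeries, start: int, end: int) -> tuple[float, float]:
    return positive_negative_work(energy, start, end)


def trial_work(
    trial,
    boundaries,
    scaled: Sequence[ScaledSegment],
    g: float = GRAVITY,
) -> tuple[WorkSummary, WorkSummary]:
    """External, internal and proxy work for both sections of a trial.

    ``trial`` carries already-filtered kinematics; ``boundaries`` is a
    :class:`~mechwork.segmentation.TrialBoundaries` (start = serve start,
    transition = change of direction into the sprint, end = CoM crossing
    the sprint threshold).  Returns the groundstroke-section and
    sprint-section summaries.  Proxy fields are ``None`` when the trial
    has no pelvis / pseudo-CoM trajectory.
    """
    rate = trial.rate
    com_series = TimeSeries(trial.com, rate)
    e_com = com_energy(com_series, trial.subject_mass, g=g)

    v_com = differentiate(com_series).values
    rel_velocities = {
        name: differentiate(TimeSeries(pos, rate)).values - v_com
        for name, pos in trial.segment_positions.items()
    }
    present = tuple(s for s in scaled if s.name in trial.segment_positions)
    unknown = set(trial.segment_positions) - {s.name for s in scaled}
    if unknown:
        raise KeyError(f"trial carries segments without scaled parameters: {sorted(unknown)}")
    limbs = limb_energies(
        rel_velocities, trial.segment_angular_velocities, present, rate,
        body_mass=trial.subject_mass,
    )

    proxies: dict[str, EnergySeries | None] = {}
    for label, track in (("pelvis", trial.pelvis), ("bb", trial.pseudo_com)):
        proxies[label] = (
            None if track is None else com_energy(TimeSeries(track, rate), trial.subject_mass, g=g)
        )

    sections = (
        ("groundstrokes", boundaries.start, boundaries.transition),
        ("sprint", boundaries.transition, boundaries.end),
    )
    summaries = []
    for section, start, end in sections:
        ext_pos, ext_neg = _section_work(e_com, start, end)
        int_pos = int_neg = 0.0
        for limb_energy in limbs.values():
            pos, neg = _section_work(limb_energy, start, end)
            int_pos += pos
            int_neg += neg
        fields: dict[str, float | None] = {
            "w_ext_pos": ext_pos, "w_ext_neg": ext_neg,
            "w_int_pos": int_pos, "w_int_neg": int_neg,
            "w_tot_pos": ext_pos + int_pos, "w_tot_neg": ext_neg + int_neg,
        }
        for label in ("pelvis", "bb"):
            energy = proxies[label]
            if energy is None:
                fields[f"w_{label}_pos"] = None
                fields[f"w_{label}_neg"] = None
            else:
                pos, neg = _section_work(energy, start, end)
                fields[f"w_{label}_pos"] = pos
                fields[f"w_{label}_neg"] = neg
        summaries.append(WorkSummary(section=section, **fields))  # type: ignore[arg-type]
    return summaries[0], summaries[1]
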