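"""Body-segment inertial parameters and whole-body centre of mass.

Segment mass, centre-of-mass and radius-of-gyration fractions follow the
de Leva adjustments of the Zatsiorsky cadaver data, collapsed onto a
14-segment model: a merged head+trunk segment, the pelvis, and bilateral
thigh/shank/foot and upper-arm/forearm/hand.  Each segment is tagged with
the limb group (``legs``, ``arms``, ``trunk``) used when internal
mechanical work is summed within limbs.

Tables ship as plain CSV (one per sex) and are renormalised on load so
that mass fractions sum to exactly 1 (the published female fractions sum
to 0.9999 after rounding).
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "LIMB_GROUPS",
    "SegmentParameters",
    "ScaledSegment",
    "load_segment_table",
    "scale_segment_parameters",
    "compute_whole_body_com",
    "default_segment_lengths",
]

LIMB_GROUPS = ("legs", "arms", "trunk")

#: Segment lengths as fractions of standing height, used when only a
#: subject's stature is known.  Order-of-magnitude anthropometry; the
#: energetics are insensitive to the exact values because segment
#: kinematics are inputs, not derived from these lengths.
_LENGTH_FRACTIONS = {
    "head_trunk": 0.470,
    "pelvis": 0.105,
    "thigh_r": 0.245,
    "thigh_l": 0.245,
    "shank_r": 0.246,
    "shank_l": 0.246,
    "foot_r": 0.152,
    "foot_l": 0.152,
    "upper_arm_r": 0.188,
    "upper_arm_l": 0.188,
    "forearm_r": 0.145,
    "forearm_l": 0.145,
    "hand_r": 0.108,
    "hand_l": 0.108,
}


@dataclass(frozen=True)
class SegmentParameters:
    """Dimensionless inertial parameters for one body segment.

    ``mass_fraction`` is the segment mass as a fraction of whole-body
    mass; ``com_fraction`` locates the segment CoM along its long axis
    from the proximal end; ``gyration_fractions`` are the three principal
    radii of gyration as fractions of segment length.
    """

    name: str
    mass_fraction: float
    com_fraction: float
    gyration_fractions: tuple[float, float, float]
    limb_group: str

    def __post_init__(self) -> None:
        if self.limb_group not in LIMB_GROUPS:
            raise ValueError(
                f"segment {self.name!r}: limb_group {self.limb_group!r} "
                f"not one of {LIMB_GROUPS}"
            )
        for label, value in (
            ("mass_fraction", self.mass_fraction),
            ("com_fraction", self.com_fraction),
            *((f"gyration_fractions[{k}]", g) for k, g in enumerate(self.gyration_fractions)),
        ):
            if not 0.0 < value < 1.0:
                raise ValueError(f"segment {self.name!r}: {label}={value} outside (0, 1)")


@dataclass(frozen=True)
class ScaledSegment:
    """Segment parameters scaled to a subject (SI units)."""

    name: str
    mass: float  # kg
    length: float  # m
    com_offset: float  # m from the proximal joint
    inertia_principal: tuple[float, float, float]  # kg m^2 about principal axes
    limb_group: str


def load_segment_table(sex: str = "male") -> tuple[SegmentParameters, ...]:
    """Load the shipped 14-segment parameter table for ``sex``.

    Mass fractions are renormalised to sum exactly to 1.
    """
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    path = resources.files("mechwork.data") / f"deleva_{sex}.csv"
    with path.open("r", newline="") as handle:
        rows = list(csv.DictReader(handle))
    total = sum(float(row["mass_fraction"]) for row in rows)
    table = tuple(
        SegmentParameters(
            name=row["name"],
            mass_fraction=float(row["mass_fraction"]) / total,
            com_fraction=float(row["com_fraction"]),
            gyration_fractions=(
                float(row["gyration_x"]),
                float(row["gyration_y"]),
                float(row["gyration_z"]),
            ),
            limb_group=row["limb_group"],
        )
        for row in rows
    )
    _check_closure(table)
    return table


def _check_closure(table: Iterable[SegmentParameters]) -> None:
    total = sum(seg.mass_fraction for seg in table)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"segment mass fractions sum to {total}, expected 1")


def scale_segment_parameters(
    body_mass: float,
    segment_lengths: Mapping[str, float],
    table: Sequence[SegmentParameters],
) -> tuple[ScaledSegment, ...]:
    """Scale a dimensionless table to a subject.

    ``mass = body_mass * mass_fraction`` and
    ``I_k = mass * (gyration_k * length)^2``; total scaled mass equals
    ``body_mass`` to closure precision.
    """
    if body_mass <= 0:
        raise ValueError(f"body_mass must be positive, got {body_mass}")
    _check_closure(table)
    scaled = []
    for seg in table:
        try:
            length = float(segment_lengths[seg.name])
        except KeyError:
            raise KeyError(
                f"no segment length supplied for segment {seg.name!r}"
            ) from None
        if length <= 0:
            raise ValueError(f"segment {seg.name!r}: non-positive length {length}")
        mass = body_mass * seg.mass_fraction
        scaled.append(
            ScaledSegment(
                name=seg.name,
                mass=mass,
                length=length,
                com_offset=seg.com_fraction * length,
                inertia_principal=tuple(
                    mass * (g * length) ** 2 for g in seg.gyration_fractions
                ),
                limb_group=seg.limb_group,
            )
        )
    return tuple(scaled)


def default_segment_lengths(height: float) -> dict[str, float]:
    """Segment lengths (m) from standing height via fixed fractions."""
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    return {name: frac * height for name, frac in _LENGTH_FRACTIONS.items()}


def compute_whole_body_com(
    segment_com_positions: Mapping[str, np.ndarray],
    scaled: Sequence[ScaledSegment],
) -> np.ndarray:
    """Mass-weighted mean of segment CoM trajectories.

    Every segment series must share the same time base; returns an
    ``(n, 3)`` array in metres.
    """
    names = [seg.name for seg in scaled]
    missing = [n for n in names if n not in segment_com_positions]
    if missing:
        raise KeyError(f"missing segment position series for: {missing}")
    arrays = [np.asarray(segment_com_positions[n], dtype=float) for n in names]
    n_samples = {a.shape[0] for a in arrays}
    if len(n_samples) != 1:
        raise ValueError(f"segment series lengths differ: {sorted(n_samples)}")
    masses = np.array([seg.mass for seg in scaled])
    stacked = np.stack(arrays, axis=0)  # (n_seg, n, 3)
    return np.einsum("s,snk->nk", masses, stacked) / masses.sum()
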