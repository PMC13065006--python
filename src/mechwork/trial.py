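"""In-memory container for one 30-s motion capture trial."""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

__all__ = ["MotionTrial"]


@dataclass
class MotionTrial:
    """Whole-body kinematics for one capture (court frame, metres).

    Court frame: x along the baseline, y forward toward the net (the
    sprint axis, origin at the baseline), z vertical up.

    ``com`` is the (n, 3) whole-body centre-of-mass trajectory;
    ``segment_positions`` maps segment name to its (n, 3) CoM trajectory
    and ``segment_angular_velocities`` to its (n, 3) angular velocity in
    the segment principal frame (rad/s).  ``pelvis`` is the pelvis-origin
    proxy trajectory; ``pseudo_com`` the triangulated bounding-box proxy
    (either may be absent).  ``bbox_observations`` optionally carries the
    raw per-camera bounding boxes from which ``pseudo_com`` can be
    reconstructed.
    """

    rate: float
    com: np.ndarray
    segment_positions: dict[str, np.ndarray]
    segment_angular_velocities: dict[str, np.ndarray]
    subject_mass: float
    sex: str = "male"
    pelvis: np.ndarray | None = None
    pseudo_com: np.ndarray | None = None
    bbox_observations: Any = None  # pandas DataFrame (camera_id, frame, cx, cy, w, h)
    player_id: str = "P00"
    cycle_index: int = 0
    extra_columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float)
        if self.com.ndim != 2 or self.com.shape[1] != 3:
            raise ValueError(f"com must be (n, 3), got {self.com.shape}")
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.subject_mass <= 0:
            raise ValueError(f"subject_mass must be positive, got {self.subject_mass}")
        n = self.n_samples
        for label, mapping in (
            ("segment_positions", self.segment_positions),
            ("segment_angular_velocities", self.segment_angular_velocities),
        ):
            for name, arr in mapping.items():
                arr = np.asarray(arr, dtype=float)
                mapping[name] = arr
                if arr.shape != (n, 3):
                    raise ValueError(
                        f"{label}[{name!r}] has shape {arr.shape}, expected {(n, 3)}"
                    )
        for label in ("pelvis", "pseudo_com"):
            arr = getattr(self, label)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                setattr(self, label, arr)
                if arr.shape != (n, 3):
                    raise ValueError(f"{label} has shape {arr.shape}, expected {(n, 3)}")

    @property
    def n_samples(self) -> int:
        return self.com.shape[0]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def with_kinematics(
        self,
        com: np.ndarray | None = None,
        segment_positions: Mapping[str, np.ndarray] | None = None,
        segment_angular_velocities: Mapping[str, np.ndarray] | None = None,
        pelvis: np.ndarray | None = None,
        pseudo_com: np.ndarray | None = None,
    ) -> "MotionTrial":
        """Copy of the trial with some kinematic streams replaced."""
        return replace(
            self,
            com=self.com if com is None else com,
            segment_positions=dict(
                self.segment_positions if segment_positions is None else segment_positions
            ),
            segment_angular_velocities=dict(
                self.segment_angular_velocities
                if segment_angular_velocities is None
                else segment_angular_velocities
            ),
            pelvis=self.pelvis if pelvis is None else pelvis,
            pseudo_com=self.pseudo_com if pseudo_com is None else pseudo_com,
        )
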