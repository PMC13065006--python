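"""Seeded synthetic motion generator for the on-court fatiguing protocol.

Generates whole cohorts of 30-s, 200-Hz trials with the structure the
analysis assumes: one serve (a prominent vertical CoM peak preceded by
countermovement minima), eight alternating groundstrokes (lateral
shuttling at the feed cadence), and a maximal sprint crossing 8.5 m
forward of the baseline, with per-player fatigue expressed as a decline
of peak sprint velocity with accumulated mechanical work.  Trajectories
are kinematic constructions (smooth envelopes plus sinusoids), not
dynamics; every downstream computation consumes kinematics only.

Each trial carries ground truth (event indices, true peak velocity,
section works computed from the noiseless skeleton) so that event
detection and work bookkeeping can be validated end to end.  Limb
oscillation amplitudes are calibrated so that internal work is roughly
one third of the total, the share reported for this protocol.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .body_model import (
    ScaledSegment,
    default_segment_lengths,
    load_segment_table,
    scale_segment_parameters,
)
from .energetics import WorkSummary, cycle_work, trial_work
from .reconstruction import CameraModel, project_point
from .segmentation import TrialBoundaries, detect_serve_start
from .signal_processing import TimeSeries, differentiate, find_local_extrema
from .trial import MotionTrial

__all__ = [
    "ProtocolConfig",
    "FatigueModel",
    "PlayerParams",
    "TrialTruth",
    "Cohort",
    "default_camera_rig",
    "simulate_trial",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Geometry and timing of the fatiguing protocol."""

    rate: float = 200.0  # Hz
    trial_duration: float = 30.0  # s
    n_groundstrokes: int = 8
    sprint_threshold: float = 8.5  # m forward of the baseline
    serve_interval_male: float = 2.0  # s between ball feeds
    serve_interval_female: float = 2.5
    lateral_amplitude: float = 2.0  # m, half the shuttle width
    rest_between_sets: float = 20.0  # s (protocol bookkeeping only)
    rest_reduction: float = 5.0  # s, removed after the listed cycles
    rest_reduction_after_cycles: tuple[int, ...] = (5, 10)
    rest_between_cycles: float = 60.0
    cycle_min: int = 4
    cycle_max: int = 12

    def __post_init__(self) -> None:
        if min(self.rate, self.trial_duration, self.sprint_threshold) <= 0:
            raise ValueError("rates, durations and thresholds must be positive")
        if not 1 <= self.cycle_min <= self.cycle_max <= 50:
            raise ValueError("cycle range must satisfy 1 <= min <= max <= 50")

    def serve_interval(self, sex: str) -> float:
        return self.serve_interval_male if sex == "male" else self.serve_interval_female


@dataclass(frozen=True)
class FatigueModel:
    """Linear fatigue: peak sprint velocity falls with accumulated work.

    ``baseline_mean``/``baseline_sd`` describe the cohort's baseline peak
    sprint velocity (m/s); per-player slopes are derived from a target
    cycle count so that a player reaches the exhaustion threshold
    (``exhaustion_fraction`` of baseline) after roughly that many cycles.
    ``noise_sd`` is trial-to-trial velocity noise (m/s).
    """

    baseline_mean: float = 6.0
    baseline_sd: float = 0.5
    noise_sd: float = 0.12
    exhaustion_fraction: float = 0.8
    target_cycles_mean: float = 6.3
    target_cycles_sd: float = 2.2

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 < self.exhaustion_fraction < 1:
            raise ValueError("exhaustion_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class PlayerParams:
    player_id: str
    sex: str
    body_mass: float  # kg
    height: float  # m
    baseline_velocity: float  # m/s
    slope: float  # velocity loss per J/kg of cumulative total work
    cycle_work_estimate: float  # J/kg, per-cycle total positive work
    scaled_segments: tuple[ScaledSegment, ...]

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("fatigue slope must be positive")


@dataclass(frozen=True)
class TrialTruth:
    """Generator ground truth for one trial."""

    serve_start: int
    transition: int
    sprint_end: int
    peak_velocity: float
    groundstroke_work: WorkSummary
    sprint_work: WorkSummary
    cycle_work: WorkSummary

    @property
    def boundaries(self) -> TrialBoundaries:
        return TrialBoundaries(self.serve_start, self.transition, self.sprint_end)


@dataclass
class Cohort:
    """A simulated cohort: players, their trials and the camera rig.

    ``trials[player_id]`` lists ``(MotionTrial, TrialTruth)`` in protocol
    order; ``cycle_index == 0`` marks the baseline sprint test, whose
    work does not count toward the cumulative load.
    """

    config: ProtocolConfig
    fatigue: FatigueModel
    seed: int
    players: list[PlayerParams] = field(default_factory=list)
    trials: dict[str, list[tuple[MotionTrial, TrialTruth]]] = field(default_factory=dict)
    cameras: dict[str, CameraModel] | None = None


# ---------------------------------------------------------------------------
# skeleton construction

# Rest offsets of segment CoMs from the whole-body CoM (m, for a 1.80 m
# subject; scaled with stature).
_REST_OFFSETS = {
    "head_trunk": (0.00, 0.00, 0.25),
    "pelvis": (0.00, -0.02, -0.10),
    "thigh_r": (0.09, 0.00, -0.35),
    "thigh_l": (-0.09, 0.00, -0.35),
    "shank_r": (0.10, 0.00, -0.60),
    "shank_l": (-0.10, 0.00, -0.60),
    "foot_r": (0.11, 0.05, -0.85),
    "foot_l": (-0.11, 0.05, -0.85),
    "upper_arm_r": (0.20, 0.00, 0.15),
    "upper_arm_l": (-0.20, 0.00, 0.15),
    "forearm_r": (0.24, 0.05, -0.05),
    "forearm_l": (-0.24, 0.05, -0.05),
    "hand_r": (0.26, 0.08, -0.20),
    "hand_l": (-0.26, 0.08, -0.20),
}

# Oscillation amplitudes (m) of segment motion relative to the CoM during
# the groundstroke and sprint phases.  The overall scale is calibrated so
# that internal work comes out near one third of the total.
_GS_AMP = {
    "head_trunk": (0.02, 0.02, 0.01),
    "pelvis": (0.03, 0.03, 0.01),
    "thigh": (0.09, 0.07, 0.02),
    "shank": (0.20, 0.15, 0.04),
    "foot": (0.27, 0.20, 0.06),
    "upper_arm": (0.14, 0.11, 0.05),
    "forearm": (0.30, 0.24, 0.10),
    "hand": (0.42, 0.33, 0.14),
}
_SPRINT_AMP = {
    "head_trunk": (0.01, 0.02, 0.01),
    "pelvis": (0.02, 0.03, 0.01),
    "thigh": (0.06, 0.12, 0.03),
    "shank": (0.10, 0.24, 0.06),
    "foot": (0.12, 0.32, 0.09),
    "upper_arm": (0.06, 0.12, 0.03),
    "forearm": (0.10, 0.20, 0.06),
    "hand": (0.12, 0.26, 0.08),
}
_GS_FREQ = {"arms": 1.5, "legs": 2.0, "trunk": 0.8}  # Hz
_SPRINT_FREQ = 2.8  # Hz stride-driven limb frequency
_ANG_AMP = {  # rad/s, segment angular velocity amplitudes
    "head_trunk": 1.0,
    "pelvis": 1.5,
    "thigh": 4.0,
    "shank": 6.0,
    "foot": 7.0,
    "upper_arm": 4.0,
    "forearm": 6.0,
    "hand": 8.0,
}
#: Global limb oscillation scale (calibrated once against the one-third
#: internal-work share).
LIMB_AMPLITUDE_SCALE = 0.5

_BOUNCE_AMP = 0.02  # m vertical oscillation during play
_BOUNCE_FREQ = 2.5  # Hz
_SERVE_PEAK_AMP = 0.45  # m, vertical excursion at the top of the serve
_SERVE_PEAK_SIGMA = 0.12  # s
_SERVE_PEAK_TIME = 1.5  # s
_GS_START = 2.5  # s, first groundstroke feed
_SPRINT_ACC_TIME = 1.5  # s to reach peak sprint velocity
_PELVIS_OFFSET = (0.0, -0.02, -0.10)
_PELVIS_SWAY_AMP = (0.04, 0.04, 0.015)  # m, stroke-frequency sway
_PELVIS_HF_AMP = (0.006, 0.006, 0.004)  # m, high-frequency wobble
_PELVIS_HF_FREQ = 4.3  # Hz (below the 6 Hz cutoff, so it survives filtering)

_POSITION_NOISE_SD = 0.002  # m
_ANGVEL_NOISE_SD = 0.05  # rad/s
_PIXEL_NOISE_SD = 1.0  # px

_HEAD_TOP = (0.0, 0.0, 0.45)  # extra keypoint offsets for bounding boxes
_FOOT_DROP = (0.0, 0.0, -0.08)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _window(t: np.ndarray, t0: float, t1: float, ramp: float = 0.5) -> np.ndarray:
    return _smoothstep((t - t0) / ramp) * _smoothstep((t1 - t) / ramp)


def _base_name(segment: str) -> str:
    return segment[:-2] if segment.endswith(("_r", "_l")) else segment


def _com_skeleton(
    t: np.ndarray,
    interval: float,
    n_gs: int,
    lateral_amp: float,
    v_peak: float,
    height: float,
    threshold: float,
) -> tuple[np.ndarray, float, float]:
    """Noiseless CoM trajectory; returns (com, t_transition, t_stop)."""
    t_gs0 = _GS_START
    t_tr = t_gs0 + n_gs * interval
    h0 = 0.55 * height

    x = np.full_like(t, lateral_amp)
    in_gs = (t >= t_gs0) & (t <= t_tr)
    x[in_gs] = lateral_amp * np.cos(np.pi * (t[in_gs] - t_gs0) / interval)

    tau = np.clip(t - t_tr, 0.0, None)
    u = np.clip(tau / _SPRINT_ACC_TIME, 0.0, 1.0)
    y_ramp = v_peak * _SPRINT_ACC_TIME * (u**2 - u**3 / 3.0)
    y = y_ramp + v_peak * np.clip(tau - _SPRINT_ACC_TIME, 0.0, None)
    # Decelerate smoothly shortly after the crossing.
    y1 = v_peak * _SPRINT_ACC_TIME * (2.0 / 3.0)
    tau_cross = _SPRINT_ACC_TIME + max(threshold - y1, 0.0) / v_peak
    tau_dec = tau_cross + 0.3
    t_dec = 1.0
    w = np.clip((tau - tau_dec) / t_dec, 0.0, 1.0)
    # Replace constant-velocity tail beyond tau_dec with a smooth stop.
    beyond = tau > tau_dec
    y_at_dec = y1 + v_peak * (tau_dec - _SPRINT_ACC_TIME)
    y[beyond] = y_at_dec + v_peak * t_dec * (w[beyond] - w[beyond] ** 2 + w[beyond] ** 3 / 3.0)

    bounce_env = _window(t, -1.0, t_tr - 0.1, ramp=0.5)
    z = h0 + _BOUNCE_AMP * bounce_env * np.sin(2.0 * np.pi * _BOUNCE_FREQ * t)
    z = z + _SERVE_PEAK_AMP * np.exp(-0.5 * ((t - _SERVE_PEAK_TIME) / _SERVE_PEAK_SIGMA) ** 2)

    com = np.stack([x, y, z], axis=-1)
    t_stop = t_tr + tau_dec + t_dec
    return com, t_tr, t_stop


def _limb_offsets(
    t: np.ndarray,
    scaled: Sequence[ScaledSegment],
    height: float,
    interval: float,
    t_tr: float,
    t_stop: float,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Segment offsets relative to the CoM and angular velocities."""
    hscale = height / 1.80
    env_gs = _window(t, 0.4, t_tr, ramp=0.5)
    env_sp = _window(t, t_tr, t_stop, ramp=0.4)
    offsets: dict[str, np.ndarray] = {}
    ang: dict[str, np.ndarray] = {}
    # Segments of a limb oscillate in phase (antiphase across sides): the
    # limb kinetic-energy ripple, and with it the internal-work share, is
    # then stable from trial to trial; a per-trial global phase plus a
    # small per-segment jitter varies the stroke timing without moving
    # that share.
    group_base = {"legs": 0.0, "arms": 1.3, "trunk": 2.1}
    trial_phase = rng.uniform(0.0, 2.0 * math.pi)
    trial_phase_sp = rng.uniform(0.0, 2.0 * math.pi)
    cadence = 2.0 / interval  # limb tempo follows the ball-feed cadence
    for idx, seg in enumerate(scaled):
        base = _base_name(seg.name)
        f_gs = _GS_FREQ[seg.limb_group] * cadence
        side = math.pi if seg.name.endswith("_l") else 0.0
        stagger = trial_phase + group_base[seg.limb_group] + side
        phase = stagger + rng.uniform(-0.05, 0.05, size=3)
        phase_sp = trial_phase_sp + group_base[seg.limb_group] + side + rng.uniform(-0.05, 0.05, size=3)
        amp_gs = np.array(_GS_AMP[base]) * LIMB_AMPLITUDE_SCALE * hscale
        amp_sp = np.array(_SPRINT_AMP[base]) * LIMB_AMPLITUDE_SCALE * hscale
        osc = (
            amp_gs * np.sin(2.0 * math.pi * f_gs * t[:, None] + phase) * env_gs[:, None]
            + amp_sp
            * np.sin(2.0 * math.pi * _SPRINT_FREQ * t[:, None] + phase_sp)
            * env_sp[:, None]
        )
        offsets[seg.name] = np.asarray(_REST_OFFSETS[seg.name]) * hscale + osc
        w_amp = _ANG_AMP[base]
        w_phase = stagger + 0.5 + rng.uniform(-0.25, 0.25, size=3)
        ang[seg.name] = (
            w_amp
            * np.sin(2.0 * math.pi * f_gs * t[:, None] + w_phase)
            * np.maximum(env_gs, env_sp)[:, None]
        )
    # Remove the mass-weighted mean so the segment cloud is consistent
    # with the prescribed whole-body CoM at every sample.
    masses = np.array([seg.mass for seg in scaled])
    mean = sum(m * offsets[seg.name] for m, seg in zip(masses, scaled)) / masses.sum()
    for seg in scaled:
        offsets[seg.name] = offsets[seg.name] - mean
    return offsets, ang


def default_camera_rig(focal: float = 800.0, image_size: tuple[int, int] = (1920, 1080)) -> dict[str, CameraModel]:
    """Eight ideal pinhole cameras around the half court."""
    positions = {
        "cam1": (-8.0, -4.0, 3.5),
        "cam2": (8.0, -4.0, 3.5),
        "cam3": (-9.0, 3.0, 3.5),
        "cam4": (9.0, 3.0, 3.5),
        "cam5": (-9.0, 9.0, 3.5),
        "cam6": (9.0, 9.0, 3.5),
        "cam7": (-6.0, 15.0, 4.5),
        "cam8": (6.0, 15.0, 4.5),
    }
    target = np.array([0.0, 5.0, 1.0])
    up = np.array([0.0, 0.0, 1.0])
    rig = {}
    for name, pos in positions.items():
        pos = np.asarray(pos, dtype=float)
        forward = target - pos
        forward /= np.linalg.norm(forward)
        right = np.cross(forward, up)
        right /= np.linalg.norm(right)
        down = np.cross(forward, right)
        rotation = np.stack([right, down, forward], axis=0)
        rig[name] = CameraModel(
            name=name,
            focal=(focal, focal),
            principal=(image_size[0] / 2.0, image_size[1] / 2.0),
            rotation=rotation,
            translation=-rotation @ pos,
            image_size=image_size,
        )
    return rig


def _bounding_boxes(
    positions: Mapping[str, np.ndarray],
    cameras: Mapping[str, CameraModel],
    hscale: float,
    rng: np.random.Generator,
    pixel_noise_sd: float,
) -> pd.DataFrame:
    """Per-camera boxes around the projected body keypoints (racket excluded)."""
    keypoints = [pos for pos in positions.values()]
    keypoints.append(positions["head_trunk"] + np.asarray(_HEAD_TOP) * hscale)
    keypoints.append(positions["foot_r"] + np.asarray(_FOOT_DROP) * hscale)
    keypoints.append(positions["foot_l"] + np.asarray(_FOOT_DROP) * hscale)
    cloud = np.stack(keypoints, axis=1)  # (n, k, 3)
    n = cloud.shape[0]
    frames = np.arange(n)
    records = []
    for name in sorted(cameras):
        pix = project_point(cameras[name], cloud)  # (n, k, 2)
        lo = pix.min(axis=1)
        hi = pix.max(axis=1)
        if pixel_noise_sd > 0:
            lo = lo + rng.normal(0.0, pixel_noise_sd, size=lo.shape)
            hi = hi + rng.normal(0.0, pixel_noise_sd, size=hi.shape)
        center = 0.5 * (lo + hi)
        size = hi - lo
        records.append(
            pd.DataFrame(
                {
                    "camera_id": name,
                    "frame": frames,
                    "cx": center[:, 0],
                    "cy": center[:, 1],
                    "w": size[:, 0],
                    "h": size[:, 1],
                }
            )
        )
    return pd.concat(records, ignore_index=True)


def _truth_events(com: np.ndarray, rate: float, t_tr: float, threshold: float) -> tuple[int, int, int]:
    z = TimeSeries(com[:, 2], rate)
    serve_start = detect_serve_start(z)
    transition = int(round(t_tr * rate))
    reached = com[:, 1] >= threshold
    if not reached.any():
        raise ValueError("configuration yields a sprint that never crosses the threshold")
    sprint_end = int(np.argmax(reached))
    return serve_start, transition, sprint_end


def simulate_trial(
    player: PlayerParams,
    cycle_index: int,
    seed: int | np.random.Generator,
    config: ProtocolConfig | None = None,
    peak_velocity: float | None = None,
    cameras: Mapping[str, CameraModel] | None = None,
    noise: bool = True,
) -> tuple[MotionTrial, TrialTruth]:
    """Generate one trial and its ground truth.

    ``peak_velocity`` defaults to the player's baseline.  With
    ``noise=False`` the returned trial is the deterministic skeleton
    (oscillation phases still come from the seed).
    """
    config = config or ProtocolConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_peak = player.baseline_velocity if peak_velocity is None else float(peak_velocity)
    interval = config.serve_interval(player.sex)
    n = int(round(config.trial_duration * config.rate))
    t = np.arange(n) / config.rate

    com, t_tr, t_stop = _com_skeleton(
        t, interval, config.n_groundstrokes, config.lateral_amplitude,
        v_peak, player.height, config.sprint_threshold,
    )
    offsets, ang = _limb_offsets(
        t, player.scaled_segments, player.height, interval, t_tr, t_stop, rng
    )
    positions = {name: com + off for name, off in offsets.items()}

    hscale = player.height / 1.80
    env_play = np.maximum(_window(t, 0.4, t_tr, 0.5), _window(t, t_tr, t_stop, 0.4))
    sway_phase = rng.uniform(0.0, 2.0 * math.pi, size=3)
    hf_phase = rng.uniform(0.0, 2.0 * math.pi, size=3)
    f_sway = _GS_FREQ["trunk"]
    pelvis = (
        com
        + np.asarray(_PELVIS_OFFSET) * hscale
        + np.asarray(_PELVIS_SWAY_AMP)
        * np.sin(2.0 * math.pi * f_sway * t[:, None] + sway_phase)
        * env_play[:, None]
        + np.asarray(_PELVIS_HF_AMP)
        * np.sin(2.0 * math.pi * _PELVIS_HF_FREQ * t[:, None] + hf_phase)
        * env_play[:, None]
    )

    serve_start, transition, sprint_end = _truth_events(
        com, config.rate, t_tr, config.sprint_threshold
    )
    boundaries = TrialBoundaries(serve_start, transition, sprint_end)

    truth_trial = MotionTrial(
        rate=config.rate,
        com=com,
        segment_positions=dict(positions),
        segment_angular_velocities=dict(ang),
        subject_mass=player.body_mass,
        sex=player.sex,
        pelvis=pelvis,
        player_id=player.player_id,
        cycle_index=cycle_index,
    )
    gs_truth, sprint_truth = trial_work(truth_trial, boundaries, player.scaled_segments)
    truth = TrialTruth(
        serve_start=serve_start,
        transition=transition,
        sprint_end=sprint_end,
        peak_velocity=v_peak,
        groundstroke_work=gs_truth,
        sprint_work=sprint_truth,
        cycle_work=cycle_work(gs_truth, sprint_truth),
    )

    if noise:
        com_out = com + rng.normal(0.0, _POSITION_NOISE_SD, size=com.shape)
        positions_out = {
            name: pos + rng.normal(0.0, _POSITION_NOISE_SD, size=pos.shape)
            for name, pos in positions.items()
        }
        ang_out = {
            name: w + rng.normal(0.0, _ANGVEL_NOISE_SD, size=w.shape)
            for name, w in ang.items()
        }
        pelvis_out = pelvis + rng.normal(0.0, _POSITION_NOISE_SD, size=pelvis.shape)
    else:
        com_out, positions_out, ang_out, pelvis_out = com, dict(positions), dict(ang), pelvis

    boxes = None
    if cameras is not None:
        boxes = _bounding_boxes(
            positions, cameras, hscale, rng, _PIXEL_NOISE_SD if noise else 0.0
        )

    trial = MotionTrial(
        rate=config.rate,
        com=com_out,
        segment_positions=positions_out,
        segment_angular_velocities=ang_out,
        subject_mass=player.body_mass,
        sex=player.sex,
        pelvis=pelvis_out,
        bbox_observations=boxes,
        player_id=player.player_id,
        cycle_index=cycle_index,
    )
    return trial, truth


def _draw_player(
    index: int,
    sex: str,
    config: ProtocolConfig,
    fatigue: FatigueModel,
    rng: np.random.Generator,
) -> PlayerParams:
    if sex == "male":
        mass = float(rng.normal(77.2, 4.7))
        height = float(np.clip(rng.normal(1.82, 0.06), 1.60, 2.05))
    else:
        mass = float(rng.normal(67.2, 10.6))
        height = float(np.clip(rng.normal(1.71, 0.05), 1.50, 1.95))
    mass = float(np.clip(mass, 45.0, 110.0))
    v0 = float(np.clip(rng.normal(fatigue.baseline_mean, fatigue.baseline_sd), 4.8, 7.2))
    n_target = float(
        np.clip(
            rng.normal(fatigue.target_cycles_mean, fatigue.target_cycles_sd),
            config.cycle_min,
            config.cycle_max,
        )
    )
    table = load_segment_table(sex)
    scaled = scale_segment_parameters(mass, default_segment_lengths(height), table)
    provisional = PlayerParams(
        player_id=f"P{index:02d}",
        sex=sex,
        body_mass=mass,
        height=height,
        baseline_velocity=v0,
        slope=1.0,  # placeholder until the work scale is known
        cycle_work_estimate=1.0,
        scaled_segments=scaled,
    )
    # One noiseless template trial pins the player's per-cycle work scale,
    # from which the fatigue slope follows.
    _, truth = simulate_trial(
        provisional, 0, np.random.default_rng(rng.integers(2**31)),
        config=config, noise=False,
    )
    w_cycle = truth.cycle_work.w_tot_pos
    slope = (1.0 - fatigue.exhaustion_fraction) * v0 / (n_target * w_cycle)
    return PlayerParams(
        player_id=provisional.player_id,
        sex=sex,
        body_mass=mass,
        height=height,
        baseline_velocity=v0,
        slope=slope,
        cycle_work_estimate=w_cycle,
        scaled_segments=scaled,
    )


def simulate_cohort(
    config: ProtocolConfig | None = None,
    fatigue: FatigueModel | None = None,
    seed: int = 0,
    n_players: int = 15,
    male_fraction: float = 10.0 / 15.0,
    with_cameras: bool = True,
    measurement_noise: bool = True,
) -> Cohort:
    """Simulate a cohort: baseline test plus cycles to volitional exhaustion.

    Each player repeats cycles until the trial's (true) peak velocity
    falls below ``exhaustion_fraction`` of baseline (checked from
    ``cycle_min`` onward) or ``cycle_max`` is reached; the sub-threshold
    cycle is completed and kept, mirroring a player stopping after the
    set that exhausts them.
    """
    if n_players < 1:
        raise ValueError("need at least one player")
    config = config or ProtocolConfig()
    fatigue = fatigue or FatigueModel()
    cameras = default_camera_rig() if with_cameras else None
    cohort = Cohort(config=config, fatigue=fatigue, seed=seed, cameras=cameras)
    streams = np.random.SeedSequence(seed).spawn(n_players)
    n_male = int(round(male_fraction * n_players))
    for index, stream in enumerate(streams, start=1):
        rng = np.random.default_rng(stream)
        sex = "male" if index <= n_male else "female"
        player = _draw_player(index, sex, config, fatigue, rng)
        cohort.players.append(player)
        records = []
        v0 = player.baseline_velocity
        baseline_v = v0 + (rng.normal(0.0, fatigue.noise_sd) if fatigue.noise_sd else 0.0)
        trial_seed = int(rng.integers(2**31))
        records.append(
            simulate_trial(player, 0, np.random.default_rng(trial_seed), config=config,
                           peak_velocity=baseline_v, cameras=cameras,
                           noise=measurement_noise)
        )
        w_cum = 0.0  # true total positive work accumulated so far
        for cycle in range(1, config.cycle_max + 1):
            trial_seed = int(rng.integers(2**31))
            # The sprint happens after the cycle's own groundstrokes, so
            # fatigue depends on the cumulative work *including* the
            # current cycle; that work in turn depends on the sprint
            # velocity.  A short fixed-point iteration (contraction rate
            # ~ slope * dW/dv << 1) makes peak velocity exactly linear in
            # the inclusive cumulative work before noise is added.
            v_target = v0 - player.slope * (w_cum + player.cycle_work_estimate)
            for _ in range(3):
                _, truth = simulate_trial(
                    player, cycle, np.random.default_rng(trial_seed), config=config,
                    peak_velocity=max(v_target, 3.5), noise=False,
                )
                v_target = v0 - player.slope * (w_cum + truth.cycle_work.w_tot_pos)
            if fatigue.noise_sd:
                v_target += rng.normal(0.0, fatigue.noise_sd)
            v_target = max(v_target, 3.5)
            trial, truth = simulate_trial(
                player, cycle, np.random.default_rng(trial_seed), config=config,
                peak_velocity=v_target, cameras=cameras, noise=measurement_noise,
            )
            records.append((trial, truth))
            w_cum += truth.cycle_work.w_tot_pos
            if cycle >= config.cycle_min and v_target < fatigue.exhaustion_fraction * v0:
                break
        cohort.trials[player.player_id] = records
    return cohort
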