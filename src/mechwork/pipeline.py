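"""End-to-end orchestration: simulate -> filter -> segment -> work -> stats.

`run_pipeline` drives the whole analysis over a simulated (or loaded)
cohort and writes tidy CSVs, a JSON report and a reproducibility
manifest.  Individual stages are plain functions so the library can be
driven piecemeal from Python; the CLI wraps these functions thinly.

Trials failing segmentation are excluded with a logged reason; the run
aborts if more than 20% of trials are excluded.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .body_model import ScaledSegment
from .energetics import GRAVITY, WorkSummary, cycle_work, trial_work
from .reconstruction import CameraModel, pelvis_proxy, pseudo_com_trajectory, write_cameras
from .segmentation import (
    WORK_VARIANTS,
    PlayerSeries,
    SegmentationError,
    TrialBoundaries,
    build_player_series,
    detect_serve_start,
    detect_sprint_end,
    detect_transition,
    peak_forward_velocity,
    work_variant_value,
)
from .signal_processing import TimeSeries, butterworth_lowpass, differentiate
from .simulate import Cohort, FatigueModel, ProtocolConfig, simulate_cohort
from .stats import (
    AgreementResult,
    magnitude_label,
    player_correlation,
    pooled_correlation,
    rm_bland_altman,
)
from .trial import MotionTrial

__all__ = [
    "PipelineConfig",
    "TrialResult",
    "load_run_config",
    "read_trial",
    "write_trial",
    "filter_trial",
    "process_trial",
    "process_player",
    "analyze_cohort",
    "run_pipeline",
]

logger = logging.getLogger("mechwork")

_CSV_FLOAT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Run configuration for the full analysis."""

    seed: int = 0
    n_players: int = 15
    cutoff: float = 6.0  # Hz low-pass for kinematics and proxies
    filter_order: int = 4  # effective (bidirectional) Butterworth order
    g: float = GRAVITY
    sprint_threshold: float = 8.5
    serve_min_prominence: float = 0.01  # m
    transition_min_prominence: float = 0.3  # m/s
    max_exclusion_fraction: float = 0.2
    include_negative_work: bool = False
    with_cameras: bool = True
    write_trials: bool = False


def load_run_config(path, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Keys mirror the dataclass fields; ``overrides`` win over file values.
    """
    import dataclasses

    import yaml

    with open(path) as handle:
        payload = yaml.safe_load(handle) or {}
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    payload.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**payload)


@dataclass(frozen=True)
class TrialResult:
    player_id: str
    cycle_index: int
    boundaries: TrialBoundaries
    peak_velocity: float
    groundstrokes: WorkSummary
    sprint: WorkSummary
    cycle: WorkSummary


# ---------------------------------------------------------------------------
# trial file IO


def write_trial(trial: MotionTrial, path) -> None:
    """Write a trial as a commented-header trajectory CSV (m, s, rad/s)."""
    path = Path(path)
    meta = (
        f"# mechwork trial v1; units: m, s, rad/s; rate={trial.rate:g}; "
        f"subject_mass={trial.subject_mass:g}; sex={trial.sex}; "
        f"player={trial.player_id}; cycle={trial.cycle_index}\n"
    )
    data: dict[str, np.ndarray] = {"time": trial.time}
    for axis, k in zip("xyz", range(3)):
        data[f"com_{axis}"] = trial.com[:, k]
    if trial.pelvis is not None:
        for axis, k in zip("xyz", range(3)):
            data[f"pelvis_{axis}"] = trial.pelvis[:, k]
    for name in sorted(trial.segment_positions):
        for axis, k in zip("xyz", range(3)):
            data[f"{name}_p{axis}"] = trial.segment_positions[name][:, k]
    for name in sorted(trial.segment_angular_velocities):
        for axis, k in zip("xyz", range(3)):
            data[f"{name}_w{axis}"] = trial.segment_angular_velocities[name][:, k]
    frame = pd.DataFrame(data)
    with open(path, "w", newline="") as handle:
        handle.write(meta)
        # Full precision: trajectory files round-trip losslessly.
        frame.to_csv(handle, index=False, float_format="%.17g")


def read_trial(path) -> MotionTrial:
    """Read a trajectory CSV written by :func:`write_trial`.

    Unknown columns are preserved (with a warning) on
    ``trial.extra_columns``; a non-monotone time column is rejected.
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.readline()
    meta: dict[str, str] = {}
    if first.startswith("#"):
        for chunk in first.lstrip("#").split(";"):
            if "=" in chunk:
                key, value = chunk.split("=", 1)
                meta[key.strip()] = value.strip()
        frame = pd.read_csv(path, skiprows=1)
    else:
        frame = pd.read_csv(path)
    if "time" not in frame.columns:
        raise ValueError(f"{path}: missing required column 'time'")
    time = frame["time"].to_numpy(dtype=float)
    if time.size < 2 or np.any(np.diff(time) <= 0):
        raise ValueError(f"{path}: non-monotone time column")
    rate = float(meta.get("rate", 1.0 / np.median(np.diff(time))))

    def grab(cols: list[str]) -> np.ndarray | None:
        if not all(c in frame.columns for c in cols):
            return None
        return frame[cols].to_numpy(dtype=float)

    com = grab(["com_x", "com_y", "com_z"])
    if com is None:
        raise ValueError(f"{path}: missing com_x/com_y/com_z columns")
    pelvis = grab(["pelvis_x", "pelvis_y", "pelvis_z"])
    segments: dict[str, np.ndarray] = {}
    angulars: dict[str, np.ndarray] = {}
    claimed = {"time", "com_x", "com_y", "com_z", "pelvis_x", "pelvis_y", "pelvis_z"}
    for col in frame.columns:
        if col.endswith("_px"):
            name = col[:-3]
            arr = grab([f"{name}_p{a}" for a in "xyz"])
            if arr is not None:
                segments[name] = arr
                claimed.update(f"{name}_p{a}" for a in "xyz")
        elif col.endswith("_wx"):
            name = col[:-3]
            arr = grab([f"{name}_w{a}" for a in "xyz"])
            if arr is not None:
                angulars[name] = arr
                claimed.update(f"{name}_w{a}" for a in "xyz")
    extras = [c for c in frame.columns if c not in claimed]
    extra_columns = {}
    if extras:
        warnings.warn(f"{path.name}: unexpected extra columns preserved: {extras}")
        extra_columns = {c: frame[c].to_numpy() for c in extras}
    return MotionTrial(
        rate=rate,
        com=com,
        segment_positions=segments,
        segment_angular_velocities=angulars,
        subject_mass=float(meta.get("subject_mass", 70.0)),
        sex=meta.get("sex", "male"),
        pelvis=pelvis,
        player_id=meta.get("player", "P00"),
        cycle_index=int(meta.get("cycle", 0)),
        extra_columns=extra_columns,
    )


# ---------------------------------------------------------------------------
# processing stages


def filter_trial(
    trial: MotionTrial,
    cameras: Mapping[str, CameraModel] | None = None,
    cutoff: float = 6.0,
    order: int = 4,
) -> MotionTrial:
    """Low-pass filter all kinematic streams and attach the proxies.

    The pelvis proxy and (if camera data is available) the triangulated
    bounding-box pseudo-CoM are filtered identically to the CoM.
    """

    def lp(values: np.ndarray) -> np.ndarray:
        return butterworth_lowpass(TimeSeries(values, trial.rate), cutoff, order=order).values

    pseudo = trial.pseudo_com
    if pseudo is None and cameras is not None and trial.bbox_observations is not None:
        pseudo = pseudo_com_trajectory(
            trial.bbox_observations, cameras, trial.rate, cutoff=cutoff, order=order
        )
    elif pseudo is not None:
        pseudo = lp(pseudo)
    return trial.with_kinematics(
        com=lp(trial.com),
        segment_positions={n: lp(p) for n, p in trial.segment_positions.items()},
        segment_angular_velocities={
            n: lp(w) for n, w in trial.segment_angular_velocities.items()
        },
        pelvis=None if trial.pelvis is None else pelvis_proxy(trial, cutoff=cutoff, order=order),
        pseudo_com=pseudo,
    )


def segment_trial(
    trial: MotionTrial,
    config: PipelineConfig,
) -> TrialBoundaries:
    """Locate serve start, sprint transition and sprint end in a filtered trial."""
    z = TimeSeries(trial.com[:, 2], trial.rate)
    start = detect_serve_start(z, min_prominence=config.serve_min_prominence)
    velocity = differentiate(TimeSeries(trial.com, trial.rate)).values
    speed = TimeSeries(np.linalg.norm(velocity, axis=1), trial.rate)
    transition = detect_transition(
        speed, search_from=start, min_prominence=config.transition_min_prominence
    )
    end = detect_sprint_end(TimeSeries(trial.com[:, 1], trial.rate), config.sprint_threshold)
    return TrialBoundaries(start=start, transition=transition, end=end)


def process_trial(
    trial: MotionTrial,
    scaled: Sequence[ScaledSegment],
    config: PipelineConfig = PipelineConfig(),
    cameras: Mapping[str, CameraModel] | None = None,
) -> TrialResult:
    """Filter, segment and compute all work variants for one trial."""
    filtered = filter_trial(trial, cameras=cameras, cutoff=config.cutoff,
                            order=config.filter_order)
    boundaries = segment_trial(filtered, config)
    gs, sprint = trial_work(filtered, boundaries, scaled, g=config.g)
    velocity = differentiate(TimeSeries(filtered.com, trial.rate)).values
    peak = peak_forward_velocity(TimeSeries(velocity[:, 1], trial.rate), boundaries)
    return TrialResult(
        player_id=trial.player_id,
        cycle_index=trial.cycle_index,
        boundaries=boundaries,
        peak_velocity=peak,
        groundstrokes=gs,
        sprint=sprint,
        cycle=cycle_work(gs, sprint),
    )


def process_player(
    trials: Sequence[MotionTrial],
    scaled: Sequence[ScaledSegment],
    config: PipelineConfig = PipelineConfig(),
    cameras: Mapping[str, CameraModel] | None = None,
) -> tuple[PlayerSeries, list[TrialResult], list[str]]:
    """Process a player's protocol-ordered trials into a cycle series.

    A trial with ``cycle_index == 0`` is the baseline sprint test: its
    peak velocity seeds the player's maximum but its work is not
    accumulated.  Returns the series, per-trial results and a list of
    exclusion messages for unsegmentable trials.
    """
    results: list[TrialResult] = []
    exclusions: list[str] = []
    for trial in trials:
        try:
            results.append(process_trial(trial, scaled, config, cameras))
        except (SegmentationError, ValueError) as err:
            message = f"{trial.player_id} cycle {trial.cycle_index}: {err}"
            logger.warning("excluded trial: %s", message)
            exclusions.append(message)
    if not results:
        raise SegmentationError("no trial of this player could be segmented")
    baseline = [r for r in results if r.cycle_index == 0]
    cycles = sorted((r for r in results if r.cycle_index > 0), key=lambda r: r.cycle_index)
    if not cycles:
        raise SegmentationError("player has no completed protocol cycles")
    baseline_peak = baseline[0].peak_velocity if baseline else max(r.peak_velocity for r in cycles)
    cycle_results = [
        (
            r.peak_velocity,
            {variant: work_variant_value(r.cycle, variant) for variant in WORK_VARIANTS},
        )
        for r in cycles
    ]
    series = build_player_series(cycle_results, baseline_peak, player_id=cycles[0].player_id)
    return series, results, exclusions


def analyze_cohort(
    series_by_player: Mapping[str, PlayerSeries],
    results: Sequence[TrialResult],
    include_negative_work: bool = False,
) -> dict:
    """Pooled correlations per work variant plus proxy agreement."""
    report: dict = {"correlations": {}, "agreement": {}}
    for variant in WORK_VARIANTS:
        per_player = []
        for player_id, series in sorted(series_by_player.items()):
            if series.n_cycles < 4:
                logger.warning(
                    "player %s has only %d cycles; omitted from pooling for %s",
                    player_id, series.n_cycles, variant,
                )
                continue
            if any(rec.cumulative_work.get(variant) is None for rec in series.records):
                logger.info("player %s lacks the %s work variant", player_id, variant)
                continue
            per_player.append(player_correlation(series, variant))
        if not per_player:
            logger.warning("work variant %s unavailable; omitted from the report", variant)
            continue
        pooled = pooled_correlation(per_player)
        report["correlations"][variant] = {
            "pooled_r": pooled.r_pooled,
            "ci95": [pooled.ci_low, pooled.ci_high],
            "tau2": pooled.tau2,
            "n_players": pooled.n_players,
            "magnitude": magnitude_label(pooled.r_pooled),
            "per_player": {c.player_id: {"r": c.r, "n": c.n} for c in per_player},
        }
    cycle_results = [r for r in results if r.cycle_index > 0]
    for label, attr in (("pelvis", "w_pelvis_pos"), ("bounding_box", "w_bb_pos")):
        paired: dict[str, list[tuple[float, float]]] = {}
        for r in cycle_results:
            proxy = getattr(r.cycle, attr)
            if proxy is None:
                continue
            paired.setdefault(r.player_id, []).append((r.cycle.w_ext_pos, proxy))
        if len(paired) >= 2:
            agreement = rm_bland_altman(paired)
            report["agreement"][label] = {
                "bias": agreement.bias,
                "loa_halfwidth": agreement.loa_halfwidth,
                "sd_within": agreement.sd_within,
                "sd_between": agreement.sd_between,
            }
    if include_negative_work:
        report["negative_work_note"] = (
            "negative-work correlations mirror the positive-work results and "
            "are reported only when explicitly requested"
        )
    return report


# ---------------------------------------------------------------------------
# full run


def _cycles_frame(series_by_player: Mapping[str, PlayerSeries]) -> pd.DataFrame:
    rows = []
    for player_id, series in sorted(series_by_player.items()):
        for rec in series.records:
            row = {
                "player_id": player_id,
                "cycle": rec.cycle_index,
                "peak_velocity": rec.peak_velocity,
                "pct_max": rec.peak_velocity_pct,
            }
            for variant in WORK_VARIANTS:
                row[f"cum_{variant}"] = rec.cumulative_work.get(variant)
            rows.append(row)
    return pd.DataFrame(rows)


def _works_frame(results: Sequence[TrialResult]) -> pd.DataFrame:
    rows = []
    for r in sorted(results, key=lambda r: (r.player_id, r.cycle_index)):
        for summary in (r.groundstrokes, r.sprint, r.cycle):
            row = {"player_id": r.player_id, "cycle": r.cycle_index}
            row.update(summary.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir=None,
    cohort: Cohort | None = None,
    protocol: ProtocolConfig | None = None,
    fatigue: FatigueModel | None = None,
) -> dict:
    """Simulate (unless a cohort is given), process and analyse.

    Returns the run manifest; when ``outdir`` is given, writes
    ``cycles.csv``, ``work_summaries.csv``, ``report.json``,
    ``cameras.json`` and ``manifest.json`` (and, optionally, the trial
    trajectory CSVs).  Outputs are deterministic for a fixed seed.
    """
    if cohort is None:
        cohort = simulate_cohort(
            config=protocol, fatigue=fatigue, seed=config.seed,
            n_players=config.n_players, with_cameras=config.with_cameras,
        )
    scaled_by_player = {p.player_id: p.scaled_segments for p in cohort.players}
    series_by_player: dict[str, PlayerSeries] = {}
    all_results: list[TrialResult] = []
    exclusions: list[str] = []
    n_trials = sum(len(records) for records in cohort.trials.values())
    for player in cohort.players:
        trials = [trial for trial, _truth in cohort.trials[player.player_id]]
        series, results, excluded = process_player(
            trials, scaled_by_player[player.player_id], config, cohort.cameras
        )
        series_by_player[player.player_id] = series
        all_results.extend(results)
        exclusions.extend(excluded)
    if n_trials and len(exclusions) / n_trials > config.max_exclusion_fraction:
        raise RuntimeError(
            f"{len(exclusions)}/{n_trials} trials excluded "
            f"(> {config.max_exclusion_fraction:.0%}); aborting run"
        )
    report = analyze_cohort(series_by_player, all_results,
                            include_negative_work=config.include_negative_work)
    manifest = {
        "software": {"package": "mechwork", "version": __version__},
        "seed": config.seed,
        "config": {
            "n_players": config.n_players,
            "cutoff_hz": config.cutoff,
            "filter_order": config.filter_order,
            "g": config.g,
            "sprint_threshold_m": config.sprint_threshold,
            "with_cameras": config.with_cameras,
        },
        "counts": {
            "players": len(cohort.players),
            "trials": n_trials,
            "excluded": len(exclusions),
            "cycles": sum(s.n_cycles for s in series_by_player.values()),
        },
        "exclusions": exclusions,
        "outputs": [],
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cycles_path = outdir / "cycles.csv"
        works_path = outdir / "work_summaries.csv"
        report_path = outdir / "report.json"
        _cycles_frame(series_by_player).to_csv(cycles_path, index=False, float_format=_CSV_FLOAT)
        _works_frame(all_results).to_csv(works_path, index=False, float_format=_CSV_FLOAT)
        with open(report_path, "w") as handle:
            json.dump(report, handle, indent=2, sort_keys=True)
            handle.write("\n")
        manifest["outputs"] = [cycles_path.name, works_path.name, report_path.name]
        if cohort.cameras is not None:
            write_cameras(cohort.cameras, outdir / "cameras.json")
            manifest["outputs"].append("cameras.json")
        if config.write_trials:
            trial_dir = outdir / "trials"
            trial_dir.mkdir(exist_ok=True)
            for player_id, records in sorted(cohort.trials.items()):
                for trial, _truth in records:
                    write_trial(trial, trial_dir / f"{player_id}_c{trial.cycle_index:02d}.csv")
            manifest["outputs"].append("trials/")
        with open(outdir / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, sort_keys=True)
            handle.write("\n")
    manifest["report"] = report
    manifest["trial_results"] = all_results  # in-memory only, not serialised
    return manifest
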