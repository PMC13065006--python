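"""Pinhole projection and least-squares ray intersection for CoM proxies.

The bounding-box pseudo-CoM is reconstructed by back-projecting each
camera's 2-D box centre as a ray from the camera centre and finding the
3-D point minimising the sum of squared perpendicular distances to all
rays — a closed-form 3x3 linear solve.  Rays whose distance to that
point exceeds an outlier threshold are discarded once and the solve is
repeated.  Cameras are ideal pinholes (no lens distortion).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .signal_processing import TimeSeries, butterworth_lowpass

__all__ = [
    "CameraModel",
    "BoundingBoxObservation",
    "TriangulationResult",
    "project_point",
    "triangulate_rays",
    "triangulate_frames",
    "pseudo_com_trajectory",
    "pelvis_proxy",
    "read_cameras",
    "write_cameras",
]


@dataclass(frozen=True)
class CameraModel:
    """Calibrated pinhole camera.

    ``rotation`` and ``translation`` map world coordinates (m) to the
    camera frame: ``x_cam = R @ x_world + t``; the optical axis is +z.
    """

    name: str
    focal: tuple[float, float]  # fx, fy in px
    principal: tuple[float, float]  # cx, cy in px
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    image_size: tuple[int, int] = (1920, 1080)

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=float))
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be (3, 3) and translation (3,)")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-9 or abs(np.linalg.det(R) - 1) > 1e-9:
            raise ValueError(f"camera {self.name!r}: rotation is not a proper rotation")
        if min(self.focal) <= 0:
            raise ValueError(f"camera {self.name!r}: focal lengths must be positive")

    @property
    def center(self) -> np.ndarray:
        """Camera centre in world coordinates."""
        return -self.rotation.T @ self.translation


@dataclass(frozen=True)
class BoundingBoxObservation:
    """One per-camera, per-frame 2-D bounding box (px)."""

    camera_id: str
    frame: int
    center: tuple[float, float]
    size: tuple[float, float]

    def __post_init__(self) -> None:
        if min(self.size) <= 0:
            raise ValueError(f"bounding box size must be positive, got {self.size}")


@dataclass(frozen=True)
class TriangulationResult:
    point: np.ndarray  # (3,)
    residuals: dict[str, float]  # ray-to-point distance (m) for the final camera set
    used: tuple[str, ...]


def project_point(camera: CameraModel, point: np.ndarray) -> np.ndarray:
    """Project world point(s) ``(..., 3)`` to pixel coordinates ``(..., 2)``."""
    pts = np.asarray(point, dtype=float)
    cam = pts @ camera.rotation.T + camera.translation
    depth = cam[..., 2]
    if np.any(depth <= 0):
        raise ValueError(f"point behind camera {camera.name!r} (non-positive depth)")
    fx, fy = camera.focal
    cx, cy = camera.principal
    u = fx * cam[..., 0] / depth + cx
    v = fy * cam[..., 1] / depth + cy
    return np.stack([u, v], axis=-1)


def _ray(camera: CameraModel, pixel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-frame origin and unit direction of the back-projected ray."""
    fx, fy = camera.focal
    cx, cy = camera.principal
    d_cam = np.array([(pixel[0] - cx) / fx, (pixel[1] - cy) / fy, 1.0])
    d = camera.rotation.T @ d_cam
    return camera.center, d / np.linalg.norm(d)


def _solve_rays(origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Point minimising sum of squared perpendicular distances to rays."""
    eye = np.eye(3)
    proj = eye[None, :, :] - dirs[:, :, None] * dirs[:, None, :]  # (k, 3, 3)
    A = proj.sum(axis=0)
    b = np.einsum("kij,kj->i", proj, origins)
    if np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError("degenerate ray geometry (parallel rays)")
    return np.linalg.solve(A, b)


def _distances(point: np.ndarray, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    rel = point[None, :] - origins
    perp = rel - np.einsum("kj,kj->k", rel, dirs)[:, None] * dirs
    return np.linalg.norm(perp, axis=1)


def triangulate_rays(
    cameras: Sequence[CameraModel],
    observations: Mapping[str, np.ndarray],
    outlier_threshold: float = 0.15,
) -> TriangulationResult:
    """Least-squares intersection of back-projected rays.

    ``observations`` maps camera name to a 2-D pixel.  After the first
    solve, rays whose perpendicular distance to the solution exceeds
    ``outlier_threshold`` (m) are discarded and the solve is repeated
    once; residuals are reported for the final camera set.
    """
    cams = [c for c in cameras if c.name in observations]
    if len(cams) < 2:
        raise ValueError(f"need at least 2 observed cameras, got {len(cams)}")
    origins = np.array([_ray(c, np.asarray(observations[c.name], dtype=float))[0] for c in cams])
    dirs = np.array([_ray(c, np.asarray(observations[c.name], dtype=float))[1] for c in cams])
    try:
        point = _solve_rays(origins, dirs)
    except np.linalg.LinAlgError as err:
        raise ValueError(f"degenerate geometry: {err}") from err
    dist = _distances(point, origins, dirs)
    # A gross outlier biases the first solve and lifts every residual;
    # requiring an outlier to also stand clear of the median keeps the
    # inliers in the second solve.
    keep = ~((dist > outlier_threshold) & (dist > 2.0 * np.median(dist)))
    if keep.sum() < 2:
        raise ValueError(
            f"fewer than 2 rays within the outlier threshold {outlier_threshold} m"
        )
    if not keep.all():
        point = _solve_rays(origins[keep], dirs[keep])
        dist = _distances(point, origins[keep], dirs[keep])
        cams = [c for c, k in zip(cams, keep) if k]
    return TriangulationResult(
        point=point,
        residuals={c.name: float(d) for c, d in zip(cams, dist)},
        used=tuple(c.name for c in cams),
    )


def triangulate_frames(
    cameras: Sequence[CameraModel],
    pixels: np.ndarray,
    outlier_threshold: float = 0.15,
) -> np.ndarray:
    """Vectorised per-frame ray intersection.

    ``pixels`` has shape ``(n_frames, n_cameras, 2)`` in the order of
    ``cameras``.  Applies the same one-pass outlier rejection per frame.
    Returns ``(n_frames, 3)`` world points.
    """
    pixels = np.asarray(pixels, dtype=float)
    n_frames, n_cams, _ = pixels.shape
    if n_cams != len(cameras) or n_cams < 2:
        raise ValueError("pixels second axis must match the camera list (>= 2 cameras)")
    origins = np.array([c.center for c in cameras])  # (k, 3)
    dirs = np.empty((n_frames, n_cams, 3))
    for j, cam in enumerate(cameras):
        fx, fy = cam.focal
        cx, cy = cam.principal
        d_cam = np.stack(
            [
                (pixels[:, j, 0] - cx) / fx,
                (pixels[:, j, 1] - cy) / fy,
                np.ones(n_frames),
            ],
            axis=-1,
        )
        d = d_cam @ cam.rotation
        dirs[:, j, :] = d / np.linalg.norm(d, axis=-1, keepdims=True)

    def solve(mask: np.ndarray) -> np.ndarray:
        proj = np.eye(3)[None, None] - dirs[:, :, :, None] * dirs[:, :, None, :]
        proj = proj * mask[:, :, None, None]
        A = proj.sum(axis=1)
        b = np.einsum("fkij,kj->fi", proj, origins)
        return np.linalg.solve(A, b[..., None])[..., 0]

    mask = np.ones((n_frames, n_cams))
    points = solve(mask)
    rel = points[:, None, :] - origins[None, :, :]
    perp = rel - np.einsum("fkj,fkj->fk", rel, dirs)[:, :, None] * dirs
    dist = np.linalg.norm(perp, axis=-1)
    med = np.median(dist, axis=1, keepdims=True)
    keep = ~((dist > outlier_threshold) & (dist > 2.0 * med))
    bad_frames = ~keep.all(axis=1)
    if bad_frames.any():
        if (keep.sum(axis=1) < 2).any():
            raise ValueError("a frame retains fewer than 2 rays after outlier rejection")
        mask2 = keep.astype(float)
        points2 = solve(mask2)
        points[bad_frames] = points2[bad_frames]
    return points


def pseudo_com_trajectory(
    boxes,
    cameras: Mapping[str, CameraModel],
    rate: float,
    cutoff: float = 6.0,
    order: int = 4,
    outlier_threshold: float = 0.15,
) -> np.ndarray:
    """Bounding-box pseudo-CoM: triangulated box centres, low-pass filtered.

    ``boxes`` is a pandas DataFrame with columns ``camera_id``, ``frame``,
    ``cx``, ``cy`` (``w``/``h`` optional).  Every frame must be seen by at
    least 2 cameras; gaps raise rather than interpolate.
    """
    frames = np.sort(boxes["frame"].unique())
    n = int(frames[-1]) + 1
    if frames.size != n or frames[0] != 0:
        missing = sorted(set(range(n)) - set(int(f) for f in frames))
        raise ValueError(f"box stream has frame gaps (first few: {missing[:5]})")
    cam_names = sorted(cameras)
    counts = boxes.groupby("frame")["camera_id"].nunique()
    if (counts < 2).any():
        bad = counts.index[counts < 2][:5].tolist()
        raise ValueError(f"frames with fewer than 2 camera views: {bad}")
    pivot_x = boxes.pivot_table(index="frame", columns="camera_id", values="cx")
    pivot_y = boxes.pivot_table(index="frame", columns="camera_id", values="cy")
    seen = [c for c in cam_names if c in pivot_x.columns]
    if len(seen) < 2:
        raise ValueError("fewer than 2 cameras present in the box stream")
    if pivot_x[seen].isna().any().any():
        # Mixed visibility: fall back to per-frame solves on observed subsets.
        points = np.empty((n, 3))
        cam_list = [cameras[c] for c in seen]
        for f in range(n):
            obs = {
                c: np.array([pivot_x.at[f, c], pivot_y.at[f, c]])
                for c in seen
                if not np.isnan(pivot_x.at[f, c])
            }
            points[f] = triangulate_rays(cam_list, obs, outlier_threshold).point
    else:
        pixels = np.stack([pivot_x[seen].to_numpy(), pivot_y[seen].to_numpy()], axis=-1)
        points = triangulate_frames([cameras[c] for c in seen], pixels, outlier_threshold)
    return butterworth_lowpass(TimeSeries(points, rate), cutoff, order=order).values


def pelvis_proxy(trial, cutoff: float = 6.0, order: int = 4) -> np.ndarray:
    """Pelvis-origin proxy trajectory, filtered identically to the CoM."""
    if trial.pelvis is None:
        raise ValueError("trial carries no pelvis trajectory")
    return butterworth_lowpass(TimeSeries(trial.pelvis, trial.rate), cutoff, order=order).values


def write_cameras(cameras: Mapping[str, CameraModel], path) -> None:
    payload = {
        name: {
            "focal": list(cam.focal),
            "principal": list(cam.principal),
            "rotation": cam.rotation.tolist(),
            "translation": cam.translation.tolist(),
            "image_size": list(cam.image_size),
        }
        for name, cam in sorted(cameras.items())
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_cameras(path) -> dict[str, CameraModel]:
    with open(path) as handle:
        payload = json.load(handle)
    return {
        name: CameraModel(
            name=name,
            focal=tuple(spec["focal"]),
            principal=tuple(spec["principal"]),
            rotation=np.array(spec["rotation"]),
            translation=np.array(spec["translation"]),
            image_size=tuple(spec["image_size"]),
        )
        for name, spec in payload.items()
    }
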