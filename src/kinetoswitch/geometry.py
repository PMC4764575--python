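"""Metaphase-plate coordinate geometry for 3D paired kinetochore tracks.

Converts raw 3D positions into the observables used throughout the
analysis: signed distance from the metaphase plate along its normal,
3D inter-sister distance, percent stretch over the relaxed (nocodazole)
rest length, and the twist angle between the sister axis and the plate
normal.  Also applies the track-length admission filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import PairedTrajectory

__all__ = [
    "PlateFit", "GeometrySeries", "REST_LENGTH_NM",
    "fit_plate", "to_plate_coords", "twist_angle", "compute_geometry",
    "filter_tracks", "longest_finite_run",
]

#: Relaxed inter-sister rest length (nm), measured under microtubule
#: depolymerisation (nocodazole).
REST_LENGTH_NM = 788.0

#: Minimum number of consecutive time points for an admissible track
#: (75% of a 150-frame movie).
MIN_CONSECUTIVE_FRAMES = 112


@dataclass
class PlateFit:
    """Per-frame metaphase-plate fit: a point on the plane and its unit
    normal, with temporally consistent normal orientation."""

    points: np.ndarray   # (F, 3) plate centroid per frame, nm
    normals: np.ndarray  # (F, 3) unit normals

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))


@dataclass
class GeometrySeries:
    """Per-frame geometric observables of one sister pair."""

    x1: np.ndarray           # signed plate-normal distance, sister 1 (nm)
    x2: np.ndarray
    d: np.ndarray            # 3D inter-sister distance (nm)
    stretch_pct: np.ndarray  # 100*(d - L0)/L0
    twist_deg: np.ndarray    # sister-axis angle to the plate normal [0, 90]
    rest_length: float = REST_LENGTH_NM


def _fit_plane_single(pts: np.ndarray, frame: int) -> tuple[np.ndarray, np.ndarray]:
    pts = np.asarray(pts, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError(f"frame {frame}: need >= 3 points to fit a plane")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # plane normal = direction of minimal variance of the cloud
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError(f"frame {frame}: degenerate (collinear) point cloud")
    return centroid, vt[2]


def fit_plate(points_per_frame: list[np.ndarray] | np.ndarray,
              per_frame: bool = True) -> PlateFit:
    """Least-squares plane through the kinetochore positions.

    With ``per_frame=True`` (default) a plane is fitted to each frame's
    point cloud, tracking plate drift; otherwise one static plane is fitted
    to all points pooled over frames.  Normal orientation is made
    consistent over time (dot product with the previous normal >= 0).
    """
    frames = [np.asarray(p, dtype=float) for p in points_per_frame]
    if not per_frame:
        centroid, normal = _fit_plane_single(np.vstack(frames), 0)
        pts = np.tile(centroid, (len(frames), 1))
        nrm = np.tile(normal, (len(frames), 1))
        return PlateFit(points=pts, normals=nrm)
    points, normals = [], []
    prev = None
    for f, pts in enumerate(frames):
        centroid, normal = _fit_plane_single(pts, f)
        if prev is not None and np.dot(normal, prev) < 0:
            normal = -normal
        prev = normal
        points.append(centroid)
        normals.append(normal)
    return PlateFit(points=np.array(points), normals=np.array(normals))


def to_plate_coords(track: np.ndarray, plate: PlateFit) -> np.ndarray:
    """Signed distance of each frame's position from the plate along its
    normal (nm)."""
    track = np.atleast_2d(np.asarray(track, dtype=float))
    return np.einsum("ij,ij->i", track - plate.points, plate.normals)


def twist_angle(p1: np.ndarray, p2: np.ndarray,
                normal: np.ndarray) -> np.ndarray:
    """Angle between the (undirected) sister axis and the plate normal,
    in degrees within [0, 90]."""
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    p2 = np.atleast_2d(np.asarray(p2, dtype=float))
    normal = np.atleast_2d(np.asarray(normal, dtype=float))
    axis = p1 - p2
    norms = np.linalg.norm(axis, axis=1)
    if np.any(norms == 0):
        raise ValueError("coincident sister positions: twist undefined")
    cosang = np.abs(np.einsum("ij,ij->i", axis, normal)) / norms
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return ang if ang.size > 1 else ang


def compute_geometry(pos1: np.ndarray, pos2: np.ndarray, plate: PlateFit,
                     rest_length: float = REST_LENGTH_NM) -> GeometrySeries:
    """All geometric observables of a sister pair from 3D positions.

    Percent stretch uses the full 3D inter-sister distance (the spring
    length), not its plate-normal projection.
    """
    pos1 = np.atleast_2d(np.asarray(pos1, dtype=float))
    pos2 = np.atleast_2d(np.asarray(pos2, dtype=float))
    d = np.linalg.norm(pos1 - pos2, axis=1)
    return GeometrySeries(
        x1=to_plate_coords(pos1, plate),
        x2=to_plate_coords(pos2, plate),
        d=d,
        stretch_pct=100.0 * (d - rest_length) / rest_length,
        twist_deg=twist_angle(pos1, pos2, plate.normals),
        rest_length=rest_length,
    )


def longest_finite_run(traj: PairedTrajectory) -> tuple[int, int]:
    """Start index and length of the longest gap-free (finite x1 and x2)
    stretch of contiguous frames."""
    ok = np.isfinite(traj.x1) & np.isfinite(traj.x2)
    n = len(ok)
    best_start = best_len = 0
    start: int | None = None
    for i in range(n + 1):
        # a missing value or a frame-number jump ends the current run
        broke = (i == n or not ok[i]
                 or (i > 0 and traj.frames[i] != traj.frames[i - 1] + 1))
        if start is not None and broke:
            if i - start > best_len:
                best_start, best_len = start, i - start
            start = None
        if i < n and ok[i] and start is None:
            start = i
    return best_start, best_len


@dataclass
class ExclusionLog:
    excluded: list[tuple[str, str]] = field(default_factory=list)  # (pair_id, reason)


def filter_tracks(tracks: list[PairedTrajectory],
                  min_frames: int = MIN_CONSECUTIVE_FRAMES,
                  ) -> tuple[list[PairedTrajectory], ExclusionLog]:
    """Keep tracks whose longest gap-free run spans >= ``min_frames``
    consecutive time points, trimmed to that run."""
    kept: list[PairedTrajectory] = []
    logbook = ExclusionLog()
    for tr in tracks:
        start, length = longest_finite_run(tr)
        if length < min_frames:
            logbook.excluded.append(
                (tr.pair_id,
                 f"longest gap-free run {length} < {min_frames} frames"))
            continue
        if length < len(tr):
            sl = slice(start, start + length)
            tr = PairedTrajectory(
                frames=tr.frames[sl], x1=tr.x1[sl], x2=tr.x2[sl], dt=tr.dt,
                pos1=None if tr.pos1 is None else tr.pos1[sl],
                pos2=None if tr.pos2 is None else tr.pos2[sl],
                pair_id=tr.pair_id, cell_id=tr.cell_id)
        kept.append(tr)
    return kept, logbook
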