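"""Bounding-box trajectories: loading, validation, gap repair and tracker scoring.

An upstream object tracker (e.g. TLD) emits one bounding box per video frame
for each tracked feature (an infant's face, a hand-held toy, a parent's
torso).  Frames where the tracker lost the target are flagged invalid; those
gaps are repaired by linear interpolation of the box center and size between
the nearest valid frames, mirroring the assumption that the tracked feature
moved linearly while unobserved.

Pixel coordinates follow the image convention: origin at the top-left
corner, y increasing downward.  Frames are 0-based and contiguous.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CSV_COLUMNS = ["frame", "x", "y", "w", "h", "valid"]


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory data."""


@dataclass(frozen=True)
class BoundingBox:
    """One tracker detection: top-left corner, size, and validity flag."""

    frame: int
    x: float
    y: float
    w: float
    h: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise TrajectoryError(f"frame index must be >= 0, got {self.frame}")
        if self.valid:
            if not (np.isfinite(self.x) and np.isfinite(self.y)):
                raise TrajectoryError(f"frame {self.frame}: non-finite coordinates on a valid box")
            if not (self.w > 0 and self.h > 0):
                raise TrajectoryError(
                    f"frame {self.frame}: valid box must have positive size, got w={self.w}, h={self.h}"
                )


@dataclass
class BoxTrajectory:
    """Per-frame bounding boxes for one tracked feature.

    Stored column-wise as numpy arrays for vectorised downstream work; the
    ``boxes`` property offers a per-frame :class:`BoundingBox` view.

    Parameters
    ----------
    x, y : array of float
        Top-left corner per frame, pixels (image coordinates, y grows down).
    w, h : array of float
        Box width and height per frame, pixels.
    valid : array of bool
        Whether the tracker reported a detection for that frame.
    fps : float
        Sampling rate in frames per second (typical video: 25).
    feature_label : str
        Free-text label such as ``"infant_face"`` or ``"object"``.
    """

    x: np.ndarray
    y: np.ndarray
    w: np.ndarray
    h: np.ndarray
    valid: np.ndarray
    fps: float = 25.0
    feature_label: str = ""
    dyad_id: str = field(default="")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.h = np.asarray(self.h, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.x)
        if not (len(self.y) == len(self.w) == len(self.h) == len(self.valid) == n):
            raise TrajectoryError("trajectory columns have mismatched lengths")
        if n < 2:
            raise TrajectoryError(f"trajectory needs at least 2 frames, got {n}")
        if self.fps <= 0:
            raise TrajectoryError(f"fps must be positive, got {self.fps}")
        v = self.valid
        if np.any(v & ((self.w <= 0) | (self.h <= 0))):
            raise TrajectoryError("valid frames must have positive box size")
        if np.any(v & ~(np.isfinite(self.x) & np.isfinite(self.y))):
            raise TrajectoryError("valid frames must have finite coordinates")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_frames(self) -> int:
        return len(self.x)

    @property
    def frames(self) -> np.ndarray:
        return np.arange(len(self.x))

    @property
    def boxes(self) -> list[BoundingBox]:
        return [
            BoundingBox(int(t), self.x[t], self.y[t], self.w[t], self.h[t], bool(self.valid[t]))
            for t in range(len(self.x))
        ]

    @property
    def centers(self) -> np.ndarray:
        """(N, 2) array of box centers ``(x + w/2, y + h/2)``."""
        return np.column_stack([self.x + self.w / 2.0, self.y + self.h / 2.0])

    def duration_s(self) -> float:
        return len(self.x) / self.fps


def load_trajectory(path, fps: float = 25.0, feature_label: str = "", dyad_id: str = "") -> BoxTrajectory:
    """Read a trajectory CSV (``frame,x,y,w,h,valid``; valid in {0,1}).

    Rows are sorted by frame; frames missing from the file are inserted as
    invalid placeholders so the output is contiguous from the first to the
    last recorded frame (re-indexed to start at 0).

    Raises
    ------
    TrajectoryError
        On an empty file, malformed rows, duplicate frame indices, or
        fewer than 2 frames.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TrajectoryError(f"{path}: cannot parse trajectory CSV: {exc}") from exc
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryError(f"{path}: missing columns {missing}")
    for col in CSV_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TrajectoryError(f"{path}: malformed value in column '{col}' at data row {row}")
    df = df.sort_values("frame").reset_index(drop=True)
    frames = df["frame"].astype(int).to_numpy()
    if len(np.unique(frames)) != len(frames):
        dup = int(frames[np.flatnonzero(np.diff(frames) == 0)[0]])
        raise TrajectoryError(f"{path}: duplicate frame index {dup}")
    if len(frames) < 2:
        raise TrajectoryError(f"{path}: need at least 2 frames, got {len(frames)}")

    span = frames[-1] - frames[0] + 1
    x = np.full(span, np.nan)
    y = np.full(span, np.nan)
    w = np.full(span, np.nan)
    h = np.full(span, np.nan)
    valid = np.zeros(span, dtype=bool)
    idx = frames - frames[0]
    x[idx] = df["x"].to_numpy(float)
    y[idx] = df["y"].to_numpy(float)
    w[idx] = df["w"].to_numpy(float)
    h[idx] = df["h"].to_numpy(float)
    valid[idx] = df["valid"].to_numpy(float).astype(bool)
    return BoxTrajectory(x, y, w, h, valid, fps=fps, feature_label=feature_label, dyad_id=dyad_id)


def save_trajectory(traj: BoxTrajectory, path) -> None:
    """Write a trajectory in the CSV schema read by :func:`load_trajectory`."""
    df = pd.DataFrame(
        {
            "frame": traj.frames,
            "x": traj.x,
            "y": traj.y,
            "w": traj.w,
            "h": traj.h,
            "valid": traj.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def tracking_accuracy(traj: BoxTrajectory) -> float:
    """Percentage of frames the tracker reported a detection for.

    This is the tracker quality score and must be computed on the raw
    trajectory, before :func:`interpolate_gaps` repairs the misses.
    """
    return 100.0 * float(np.count_nonzero(traj.valid)) / len(traj)


def interpolate_gaps(traj: BoxTrajectory) -> tuple[BoxTrajectory, int]:
    """Fill invalid frames by linear interpolation of box center and size.

    Interior gaps are interpolated between the last valid frame before and
    the first valid frame after the gap.  Gaps touching the first or last
    frame have no bracketing point on one side and are filled by
    nearest-valid constant extrapolation (with a warning).

    Returns
    -------
    (repaired, n_interpolated)
        A fully valid trajectory and the number of frames that were filled.
    """
    valid_idx = np.flatnonzero(traj.valid)
    if valid_idx.size == 0:
        raise TrajectoryError("trajectory has no valid frames; nothing to interpolate from")
    n_interp = int(len(traj) - valid_idx.size)
    if n_interp == 0:
        return replace(traj), 0
    if valid_idx[0] != 0 or valid_idx[-1] != len(traj) - 1:
        warnings.warn(
            "gap touches trajectory boundary; filled by nearest-valid extrapolation",
            stacklevel=2,
        )
    t = np.arange(len(traj))
    # np.interp clamps outside the valid range, giving the edge extrapolation
    cx = np.interp(t, valid_idx, traj.x[valid_idx] + traj.w[valid_idx] / 2.0)
    cy = np.interp(t, valid_idx, traj.y[valid_idx] + traj.h[valid_idx] / 2.0)
    w = np.interp(t, valid_idx, traj.w[valid_idx])
    h = np.interp(t, valid_idx, traj.h[valid_idx])
    out = BoxTrajectory(
        cx - w / 2.0,
        cy - h / 2.0,
        w,
        h,
        np.ones(len(traj), dtype=bool),
        fps=traj.fps,
        feature_label=traj.feature_label,
        dyad_id=traj.dyad_id,
    )
    return out, n_interp


def repair_report(traj: BoxTrajectory) -> dict:
    """Score and repair a trajectory; return the JSON-ready sidecar record."""
    acc = tracking_accuracy(traj)
    repaired, n_interp = interpolate_gaps(traj)
    return {
        "trajectory": repaired,
        "accuracy_percent": acc,
        "n_interpolated": n_interp,
        "n_frames": len(traj),
    }


def write_sidecar(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {k: report[k] for k in ("accuracy_percent", "n_interpolated", "n_frames")},
            fh,
            indent=2,
        )


def trim_pair(a, b):
    """Trim the longer of two categorical series to the length of the shorter.

    Only trailing elements are removed, so the retained parts stay aligned
    at the start of the episode.  Both series must share a sampling rate.
    """
    if len(a.codes) == 0 or len(b.codes) == 0:
        raise TrajectoryError("cannot trim empty series")
    if a.fps != b.fps:
        raise TrajectoryError(f"fps mismatch: {a.fps} vs {b.fps}")
    n = min(len(a.codes), len(b.codes))
    return a.head(n), b.head(n)
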