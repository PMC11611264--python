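"""Fly tracks: containers, file I/O, gap handling and smoothing.

A track is one fly's head coordinates sampled at a nominal 25 frames/s.
Tracks are exchanged as plain comma-separated tables with columns
``fly_id, t_s, x_mm, y_mm`` (one row per fly per frame), the format every
pipeline stage reads and writes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .arena import ArenaSpec, IlluminationEpoch, validate_schedule

log = logging.getLogger(__name__)

TRACK_COLUMNS = ["fly_id", "t_s", "x_mm", "y_mm"]


@dataclass
class FlyTrack:
    """Time-stamped head coordinates of a single fly.

    ``valid_mask`` flags frames with trustworthy coordinates; out-of-range
    or missing samples are kept in place (so frame indexing is stable) but
    excluded from every time, occupancy and speed sum.
    """

    fly_id: str
    frame_times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.frame_times.shape, dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = len(self.frame_times)
        if not (len(self.x) == len(self.y) == len(self.valid_mask) == n):
            raise ValueError("track series must have equal length")
        if n == 0:
            raise ValueError("empty track")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError(f"non-monotone timestamps for fly {self.fly_id!r}")

    def __len__(self) -> int:
        return len(self.frame_times)

    @property
    def median_dt(self) -> float:
        if len(self) < 2:
            return 0.04
        return float(np.median(np.diff(self.frame_times)))

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of frames with t0 <= t < t1."""
        return (self.frame_times >= t0) & (self.frame_times < t1)


@dataclass
class ExperimentRecord:
    """One genotype group: tracks plus arena, schedule and metadata."""

    tracks: list[FlyTrack]
    arena: ArenaSpec
    schedule: list[IlluminationEpoch]
    group_label: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError("group_label must be non-empty")
        validate_schedule(self.schedule)

    def __len__(self) -> int:
        return len(self.tracks)


class TrackFormatError(ValueError):
    """Raised when a track table is missing required columns."""


def _validate_coords(track: FlyTrack, arena: ArenaSpec) -> FlyTrack:
    in_range = (
        (track.x >= 0)
        & (track.x <= arena.length)
        & (track.y >= 0)
        & (track.y <= arena.width)
        & np.isfinite(track.x)
        & np.isfinite(track.y)
    )
    bad = track.valid_mask & ~in_range
    if bad.any():
        log.warning(
            "fly %s: %d frame(s) outside the %.0fx%.0f mm arena marked invalid",
            track.fly_id, int(bad.sum()), arena.length, arena.width,
        )
    track.valid_mask = track.valid_mask & in_range
    return track


def load_tracks(
    path,
    arena: ArenaSpec,
    schedule: Sequence[IlluminationEpoch],
    group_label: str = "group",
    metadata: dict | None = None,
) -> ExperimentRecord:
    """Read a track table (CSV: fly_id, t_s, x_mm, y_mm) into a record.

    Rows are sorted by time within each fly; coordinates outside the arena
    are flagged invalid (never clamped); non-monotone timestamps raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"track table {path} missing columns: {missing}")
    tracks = []
    for fly_id, sub in df.groupby("fly_id", sort=True):
        sub = sub.sort_values("t_s", kind="stable")
        track = FlyTrack(
            fly_id=str(fly_id),
            frame_times=sub["t_s"].to_numpy(float),
            x=sub["x_mm"].to_numpy(float),
            y=sub["y_mm"].to_numpy(float),
        )
        tracks.append(_validate_coords(track, arena))
    return ExperimentRecord(
        tracks=tracks,
        arena=arena,
        schedule=list(schedule),
        group_label=group_label,
        metadata=metadata or {},
    )


def write_tracks(record: ExperimentRecord, path) -> None:
    """Write a record's tracks as the standard CSV table (valid frames keep
    their coordinates; all frames are written)."""
    frames = []
    for t in record.tracks:
        frames.append(
            pd.DataFrame(
                {"fly_id": t.fly_id, "t_s": t.frame_times, "x_mm": t.x, "y_mm": t.y}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def fill_short_gaps(track: FlyTrack, max_gap_s: float = 0.2) -> FlyTrack:
    """Linearly interpolate invalid runs no longer than ``max_gap_s``.

    Short dropouts are bridged (and re-marked valid) so smoothing and speed
    sums stay continuous; longer gaps are left invalid and excluded
    downstream.
    """
    valid = track.valid_mask.copy()
    if valid.all() or not valid.any():
        return track
    x = track.x.copy()
    y = track.y.copy()
    t = track.frame_times
    idx = np.flatnonzero(~valid)
    # group consecutive invalid indices into runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        i0, i1 = run[0], run[-1]
        if i0 == 0 or i1 == len(t) - 1:
            continue  # edge gaps cannot be interpolated
        if not (valid[i0 - 1] and valid[i1 + 1]):
            continue
        if t[i1 + 1] - t[i0 - 1] > max_gap_s + 1e-9:
            continue
        frac = (t[run] - t[i0 - 1]) / (t[i1 + 1] - t[i0 - 1])
        x[run] = x[i0 - 1] + frac * (x[i1 + 1] - x[i0 - 1])
        y[run] = y[i0 - 1] + frac * (y[i1 + 1] - y[i0 - 1])
        valid[run] = True
    return replace(track, x=x, y=y, valid_mask=valid)


def triangular_kernel(n: int) -> np.ndarray:
    """Centered triangular weights of odd length n, summing to 1."""
    if n < 1:
        raise ValueError("kernel length must be >= 1")
    if n % 2 == 0:
        n += 1
    half = n // 2
    w = 1.0 - np.abs(np.arange(n) - half) / (half + 1.0)
    return w / w.sum()


def smooth_track(track: FlyTrack, window: float = 1.0) -> FlyTrack:
    """Centered triangular rolling smoothing of x and y.

    The kernel spans ``window`` seconds (25 frames at the nominal rate,
    taken from the track's own timestamps).  Weights are renormalised at
    the track edges and across invalid frames, so the smoothed value is
    always a convex combination of valid samples; the valid mask is
    preserved.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if not track.valid_mask.any():
        raise ValueError("cannot smooth a track with no valid frames")
    track = fill_short_gaps(track)
    dt = track.median_dt
    n = max(1, int(round(window / dt)))
    if n % 2 == 0:
        n += 1
    kernel = triangular_kernel(n)
    v = track.valid_mask.astype(float)
    half = len(kernel) // 2

    def conv_centered(sig: np.ndarray) -> np.ndarray:
        # np.convolve 'same' misbehaves for signals shorter than the
        # kernel; take the centre of the full convolution explicitly
        return np.convolve(sig, kernel, mode="full")[half : half + len(sig)]

    out = {}
    for name in ("x", "y"):
        sig = getattr(track, name) * v
        num = conv_centered(sig)
        den = conv_centered(v)
        sm = np.where(den > 0, num / np.where(den > 0, den, 1.0), getattr(track, name))
        # invalid frames keep their original (unused) coordinates
        sm = np.where(track.valid_mask, sm, getattr(track, name))
        out[name] = sm
    return replace(track, x=out["x"], y=out["y"])
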