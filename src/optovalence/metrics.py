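"""Per-fly preference and speed metrics.

For every fly and illumination epoch the pipeline scores, over the last
30 s of the epoch:

* ``PI`` — Preference Index, (time in light - time in dark) / total time,
  in [-1, +1].  A fly that stayed on one side for the whole epoch but
  still moved within it is assigned the corresponding extreme PI (+1.0 or
  -1.0) and flagged ``extreme_assigned``.
* ``LSR`` — log2 Speed Ratio, log2(mean speed in light / mean speed in
  dark), computed only for flies that moved in both lit and unlit regions;
  flies stationary for the whole epoch, or confined to one side, are
  censored from the speed ratio (never from PI).

Time is integrated as inter-frame intervals rather than frame counts, so
irregular sampling degrades gracefully; each step's displacement is
attributed to the zone of its starting frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .arena import ArenaSpec, IlluminationEpoch
from .track import FlyTrack, smooth_track
from .zones import ZoneAnnotation, annotate_zones

log = logging.getLogger(__name__)

#: Minimum within-epoch path length (mm) counted as "moved"; used both for
#: the extreme-PI assignment and for the stationary-fly LSR exclusion.
MIN_PATH_MM = 2.0

#: Analysis window: metrics are scored over the last 30 s of each epoch.
ANALYSIS_WINDOW_S = 30.0

# censor flags
NO_MOVEMENT = "no_movement"
SINGLE_ZONE = "single_zone"
NO_LIGHT_FRAMES = "no_light_frames"
NO_DARK_FRAMES = "no_dark_frames"
NO_VALID_FRAMES = "no_valid_frames"


@dataclass
class FlyEpochMetrics:
    """Preference and speed statistics for one fly in one epoch."""

    fly_id: str
    epoch_label: str
    pi: float = np.nan
    pi_source: str = "measured"  # or "extreme_assigned"
    lsr: float = np.nan
    time_in_light: float = 0.0
    time_in_dark: float = 0.0
    mean_speed_light: float = np.nan
    mean_speed_dark: float = np.nan
    path_length: float = 0.0
    censor_flags: set = field(default_factory=set)

    @property
    def pi_censored(self) -> bool:
        return not np.isfinite(self.pi)

    @property
    def lsr_censored(self) -> bool:
        return not np.isfinite(self.lsr)


def _frame_dts(times: np.ndarray, median_dt: float) -> np.ndarray:
    """Occupancy weight of each frame: interval to the next frame, with the
    last frame (and any long dropout gap) credited one nominal interval."""
    if len(times) == 0:
        return np.zeros(0)
    dts = np.empty(len(times))
    dts[:-1] = np.diff(times)
    dts[-1] = median_dt
    long = dts > 3.0 * median_dt
    dts[long] = median_dt
    return dts


def _window_mask(ann: ZoneAnnotation, window_s: float) -> np.ndarray:
    t0 = max(ann.epoch.start, ann.epoch.end - window_s)
    return ann.times >= t0


def _path_length(track: FlyTrack, ann: ZoneAnnotation) -> float:
    idx = ann.frame_index
    ok = ann.valid[:-1] & ann.valid[1:] if len(idx) > 1 else np.zeros(0, bool)
    dx = np.diff(track.x[idx])
    dy = np.diff(track.y[idx])
    return float(np.sum(np.hypot(dx, dy)[ok]))


def compute_pi(
    track: FlyTrack,
    annotation: ZoneAnnotation,
    window_s: float = ANALYSIS_WINDOW_S,
    metrics: FlyEpochMetrics | None = None,
) -> FlyEpochMetrics:
    """Preference index over the last ``window_s`` seconds of the epoch."""
    ann = annotation
    m = metrics or FlyEpochMetrics(track.fly_id, ann.epoch.label or str(ann.epoch.start))
    m.path_length = _path_length(track, ann)
    win = _window_mask(ann, window_s) & ann.valid
    if not win.any():
        m.censor_flags.add(NO_VALID_FRAMES)
        return m
    dts = _frame_dts(ann.times, track.median_dt)
    t_light = float(np.sum(dts[win & ann.lit]))
    t_dark = float(np.sum(dts[win & ~ann.lit]))
    m.time_in_light, m.time_in_dark = t_light, t_dark
    total = t_light + t_dark
    m.pi = (t_light - t_dark) / total
    # single-sided fly for the whole epoch, but moving: extreme assignment
    epoch_states = ann.lit[ann.valid]
    if epoch_states.size and m.path_length > MIN_PATH_MM:
        if epoch_states.all():
            m.pi, m.pi_source = 1.0, "extreme_assigned"
        elif not epoch_states.any():
            m.pi, m.pi_source = -1.0, "extreme_assigned"
    return m


def step_speeds(
    track: FlyTrack, annotation: ZoneAnnotation
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-step speed (mm/s) with the lit state, time and annotation index
    of each step's start frame."""
    ann = annotation
    idx = ann.frame_index
    if len(idx) < 2:
        z = np.zeros(0)
        return z, z.astype(bool), z, z.astype(int)
    dt = np.diff(track.frame_times[idx])
    dx = np.diff(track.x[idx])
    dy = np.diff(track.y[idx])
    ok = ann.valid[:-1] & ann.valid[1:] & (dt <= 3.0 * track.median_dt)
    speed = np.hypot(dx, dy)[ok] / dt[ok]
    start = np.flatnonzero(ok)
    return speed, ann.lit[:-1][ok], ann.times[:-1][ok], start


#: Speed samples closer than this to a light/dark border crossing are
#: excluded from the zone means.  Within half the 1 s smoothing window of a
#: crossing the smoothed velocity mixes the two speed regimes (and the
#: smoothed position is displaced toward the slower side), so these
#: samples are informative about neither zone; keeping them systematically
#: shrinks the measured speed ratio toward zero.  For the same reason, the
#: speed ratio uses only "cruise" samples from the quadrant interiors:
#: steps starting inside a choice zone, or within a wall margin of the
#: arena ends, sit where boundary turning dips the smoothed speed.  Border
#: (and wall) encounters per unit occupancy scale with the local walking
#: speed, so boundary-localised dips attenuate the faster zone's mean
#: disproportionately and bias the ratio toward 1 if included.  The buffer
#: is deliberately shorter than the full kernel half-width: requiring a
#: fully event-free kernel support selects against short fast bouts and
#: re-biases the fast zone's mean downward, so 0.25 s balances residual
#: kernel overlap against bout-selection bias (validated on simulator
#: ground truth across speed ratios of 0.5-2).
TRANSITION_BUFFER_S = 0.25

#: Wall margin (mm) excluded from speed-ratio samples at the arena ends.
WALL_MARGIN_MM = 3.0


def _crossing_times(ann: ZoneAnnotation) -> np.ndarray:
    lit = ann.lit[ann.valid]
    t = ann.times[ann.valid]
    if lit.size < 2:
        return np.zeros(0)
    flips = np.flatnonzero(lit[1:] != lit[:-1])
    return 0.5 * (t[flips] + t[flips + 1])


#: Minimum sustained x-velocity (mm/s) for heading-reversal detection;
#: below this the fly is effectively paused and sign flips are jitter.
TURN_DETECT_MIN_SPEED = 1.0


def _turn_times(track: FlyTrack, ann: ZoneAnnotation) -> np.ndarray:
    """Times of heading reversals along x, from the smoothed track.

    The x-velocity is block-averaged over ~0.2 s and a reversal is a sign
    flip between successive clearly-moving samples, so pause jitter does
    not register as turning.
    """
    idx = ann.frame_index[ann.valid]
    if idx.size < 3:
        return np.zeros(0)
    t = track.frame_times[idx]
    vx = np.diff(track.x[idx]) / np.diff(t)
    k = max(1, int(round(0.2 / track.median_dt)))
    if k > 1 and vx.size >= k:
        kernel = np.full(k, 1.0 / k)
        vx = np.convolve(vx, kernel, mode="same")
    s = np.sign(vx) * (np.abs(vx) > TURN_DETECT_MIN_SPEED)
    nz = np.flatnonzero(s != 0)
    if nz.size < 2:
        return np.zeros(0)
    flips = nz[1:][s[nz[1:]] != s[nz[:-1]]]
    return t[flips]


def compute_lsr(
    track: FlyTrack,
    annotation: ZoneAnnotation,
    window_s: float = ANALYSIS_WINDOW_S,
    metrics: FlyEpochMetrics | None = None,
    transition_buffer_s: float = TRANSITION_BUFFER_S,
    arena: ArenaSpec | None = None,
) -> FlyEpochMetrics:
    """log2 speed ratio over the analysis window, with exclusion rules.

    Expects a smoothed track (see :func:`smooth_track`); speeds are taken
    from the coordinates as given, restricted to cruise samples: outside
    choice zones, clear of the arena ends (when ``arena`` is supplied) and
    at least ``transition_buffer_s`` from any border crossing (see
    :data:`TRANSITION_BUFFER_S`).
    """
    ann = annotation
    m = metrics or FlyEpochMetrics(track.fly_id, ann.epoch.label or str(ann.epoch.start))
    if m.path_length == 0.0:
        m.path_length = _path_length(track, ann)
    if m.path_length <= MIN_PATH_MM:
        m.censor_flags.add(NO_MOVEMENT)
        return m
    speed, lit, t_start, start_idx = step_speeds(track, ann)
    t0 = max(ann.epoch.start, ann.epoch.end - window_s)
    win = t_start >= t0
    if transition_buffer_s > 0 and win.any():
        events = np.concatenate([_crossing_times(ann), _turn_times(track, ann)])
        if events.size:
            gap = np.min(np.abs(t_start[:, None] - events[None, :]), axis=1)
            win &= gap >= transition_buffer_s
    # cruise samples only: outside choice zones and away from the walls
    win &= ann.choice_zone[start_idx] < 0
    if arena is not None:
        x_start = track.x[ann.frame_index[start_idx]]
        win &= (x_start >= WALL_MARGIN_MM) & (x_start <= arena.length - WALL_MARGIN_MM)
    lit_speeds = speed[win & lit]
    dark_speeds = speed[win & ~lit]
    if lit_speeds.size == 0 or not np.any(lit_speeds > 0):
        m.censor_flags.add(NO_LIGHT_FRAMES)
    if dark_speeds.size == 0 or not np.any(dark_speeds > 0):
        m.censor_flags.add(NO_DARK_FRAMES)
    if m.censor_flags & {NO_LIGHT_FRAMES, NO_DARK_FRAMES}:
        m.censor_flags.add(SINGLE_ZONE)
        return m
    mean_light = float(np.mean(lit_speeds))
    mean_dark = float(np.mean(dark_speeds))
    if mean_light <= 0 or mean_dark <= 0:  # division guard
        m.censor_flags.add(SINGLE_ZONE)
        return m
    m.mean_speed_light, m.mean_speed_dark = mean_light, mean_dark
    m.lsr = float(np.log2(mean_light / mean_dark))
    return m


@dataclass
class ConditioningResult:
    """Olfactory-conditioning preference score.

    Each testing phase yields a half performance index from the last 30 s
    of fly positions: (time on the CS+ side - time on the CS- side) /
    total.  The two phases swap odor sides; their mean is the full PI, so
    any fixed side bias cancels.  Positive full PI = preference for the
    CS+ odor.
    """

    half_pi_a: float
    half_pi_b: float

    @property
    def full_pi(self) -> float:
        return 0.5 * (self.half_pi_a + self.half_pi_b)


def _half_pi(
    tracks: list[FlyTrack], cs_plus_side: str, midline: float, window_s: float
) -> float:
    t_plus = t_minus = 0.0
    for tr in tracks:
        t_end = tr.frame_times[-1]
        sel = (tr.frame_times >= t_end - window_s) & tr.valid_mask
        dts = _frame_dts(tr.frame_times[sel], tr.median_dt)
        on_right = tr.x[sel] >= midline
        right_t = float(np.sum(dts[on_right]))
        left_t = float(np.sum(dts[~on_right]))
        if cs_plus_side == "right":
            t_plus += right_t
            t_minus += left_t
        else:
            t_plus += left_t
            t_minus += right_t
    total = t_plus + t_minus
    if total == 0:
        raise ValueError("no valid position data in the testing window")
    return (t_plus - t_minus) / total


def compute_conditioning_pi(
    phase_a_tracks: list[FlyTrack],
    phase_b_tracks: list[FlyTrack],
    cs_plus_side_a: str,
    midline: float,
    window_s: float = ANALYSIS_WINDOW_S,
) -> ConditioningResult:
    """Full conditioning PI from the two testing phases.

    ``cs_plus_side_a`` ('left' or 'right') gives the CS+ odor side in
    phase A; phase B presents the swapped arrangement.
    """
    if not phase_a_tracks or not phase_b_tracks:
        raise ValueError("both testing phases are required")
    if cs_plus_side_a not in ("left", "right"):
        raise ValueError("cs_plus_side_a must be 'left' or 'right'")
    side_b = "right" if cs_plus_side_a == "left" else "left"
    return ConditioningResult(
        half_pi_a=_half_pi(phase_a_tracks, cs_plus_side_a, midline, window_s),
        half_pi_b=_half_pi(phase_b_tracks, side_b, midline, window_s),
    )


def fly_epoch_metrics(
    track: FlyTrack,
    arena: ArenaSpec,
    epoch: IlluminationEpoch,
    window_s: float = ANALYSIS_WINDOW_S,
    smooth: bool = True,
) -> FlyEpochMetrics:
    """Convenience: smooth, annotate, then compute PI and LSR for one fly."""
    sm = smooth_track(track) if smooth else track
    ann = annotate_zones(sm, arena, epoch)
    m = compute_pi(sm, ann, window_s)
    return compute_lsr(sm, ann, window_s, metrics=m, arena=arena)


def summarize_group(
    record,
    epochs: list[IlluminationEpoch] | None = None,
    window_s: float = ANALYSIS_WINDOW_S,
    include_choice: bool = True,
    smooth: bool = True,
) -> pd.DataFrame:
    """Tidy per-fly, per-epoch metric table for one experiment group.

    One row per fly per epoch with PI, LSR, choice metrics and explicit
    censor flags; group summaries downstream average only non-censored
    values per metric.
    """
    from .choice import choice_metrics_for_track  # local import, avoids cycle

    epochs = epochs if epochs is not None else record.schedule
    rows = []
    for track in record.tracks:
        sm = smooth_track(track) if smooth else track
        for epoch in epochs:
            ann = annotate_zones(sm, record.arena, epoch)
            m = compute_pi(sm, ann, window_s)
            m = compute_lsr(sm, ann, window_s, metrics=m, arena=record.arena)
            row = {
                "group": record.group_label,
                "fly_id": m.fly_id,
                "epoch": m.epoch_label,
                "intensity_uW_mm2": epoch.intensity,
                "pi": m.pi,
                "pi_source": m.pi_source,
                "lsr": m.lsr,
                "time_in_light_s": m.time_in_light,
                "time_in_dark_s": m.time_in_dark,
                "mean_speed_light": m.mean_speed_light,
                "mean_speed_dark": m.mean_speed_dark,
                "censor_flags": ";".join(sorted(m.censor_flags)),
            }
            if include_choice:
                cm = choice_metrics_for_track(sm, record.arena, epoch)
                row.update(
                    {
                        "chi": cm.chi,
                        "pedl": cm.pedl,
                        "peld": cm.peld,
                        "n_transits": cm.n_transits,
                    }
                )
            rows.append(row)
    return pd.DataFrame(rows)
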