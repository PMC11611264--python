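"""Choice-zone transit segmentation and boundary statistics.

A choice zone extends 3 mm either side of each light/dark border.  A
transit opens when a fly's head enters a zone from outside and closes at
the first frame outside that zone again; the entry and exit sides take the
lit/unlit state of the quadrant immediately adjacent to the border on that
side.  Per fly and epoch:

* ``ChI`` — Choice Index, (transits exiting to light - exiting to dark) /
  total transits.
* ``PEDL`` — proportion of entries from the dark side that exit to light.
* ``PELD`` — proportion of entries from the light side that exit to dark.

Metrics are computed for every fly that entered a choice zone at least
once during the epoch; flies that never approached a border are censored
from the choice analysis entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arena import ArenaSpec, IlluminationEpoch
from .track import FlyTrack
from .zones import NO_ZONE, ZoneAnnotation, annotate_zones

LIGHT = "light"
DARK = "dark"

#: A re-entry within this many frames of the previous exit at the same
#: border is treated as tracking chatter and merged into the prior transit.
CHATTER_MERGE_FRAMES = 2


@dataclass
class Transit:
    """One passage in and out of a choice zone."""

    fly_id: str
    border: int
    t_entry: float
    t_exit: float
    entry_side: str  # light / dark state of the side entered from
    exit_side: str
    entry_dir: str  # "left" / "right": geometric side entered from
    exit_dir: str
    x_min: float
    x_max: float
    i_entry: int  # annotation frame index of first in-zone frame
    i_exit: int  # annotation frame index of first outside frame

    @property
    def outcome(self) -> str:
        return "crossing" if self.exit_dir != self.entry_dir else "reversal"


@dataclass
class ChoiceMetrics:
    """Per-fly choice statistics; NaN marks a censored value."""

    fly_id: str
    chi: float = np.nan
    pedl: float = np.nan
    peld: float = np.nan
    n_transits: int = 0
    n_entries_from_dark: int = 0
    n_entries_from_light: int = 0

    @property
    def censored(self) -> bool:
        return self.n_transits == 0


def _side_state(border: int, direction: str, epoch: IlluminationEpoch) -> str:
    """Lit/unlit state of the quadrant adjacent to ``border`` on a side."""
    quadrant = border if direction == "left" else border + 1
    lit = (not epoch.is_dark) and quadrant in epoch.lit_quadrants
    return LIGHT if lit else DARK


def segment_transits(
    track: FlyTrack,
    annotation: ZoneAnnotation,
    arena: ArenaSpec,
    merge_frames: int = CHATTER_MERGE_FRAMES,
) -> list[Transit]:
    """Segment all choice-zone transits of one fly during one epoch.

    A partial transit already underway at epoch start is discarded (its
    entry side is unknown), as is a transit still open at epoch end.
    Invalid frames are skipped.
    """
    ann = annotation
    ok = np.flatnonzero(ann.valid)
    if ok.size < 2:
        return []
    zone = ann.choice_zone[ok]
    x = track.x[ann.frame_index][ok]
    t = ann.times[ok]
    borders = arena.border_positions
    epoch = ann.epoch

    transits: list[Transit] = []
    open_t: dict | None = None
    # skip a partial transit underway at the first valid frame
    j0 = 0
    if zone[0] != NO_ZONE:
        k0 = zone[0]
        while j0 < len(zone) and zone[j0] == k0:
            j0 += 1
    for j in range(max(j0, 1), len(zone)):
        z_prev, z_now = zone[j - 1], zone[j]
        if z_now == z_prev:
            if open_t is not None:
                open_t["x_min"] = min(open_t["x_min"], x[j])
                open_t["x_max"] = max(open_t["x_max"], x[j])
            continue
        if open_t is not None:  # leaving zone open_t["border"]
            b = borders[open_t["border"]]
            exit_dir = "left" if x[j] < b else "right"
            transits.append(
                Transit(
                    fly_id=ann.fly_id,
                    border=open_t["border"],
                    t_entry=open_t["t_entry"],
                    t_exit=t[j],
                    entry_side=_side_state(open_t["border"], open_t["entry_dir"], epoch),
                    exit_side=_side_state(open_t["border"], exit_dir, epoch),
                    entry_dir=open_t["entry_dir"],
                    exit_dir=exit_dir,
                    x_min=open_t["x_min"],
                    x_max=open_t["x_max"],
                    i_entry=open_t["i_entry"],
                    i_exit=ok[j],
                )
            )
            open_t = None
        if z_now != NO_ZONE:  # entering zone z_now
            b = borders[z_now]
            entry_dir = "left" if x[j - 1] < b else "right"
            i_entry = ok[j]
            # chatter suppression: quick re-entry continues the last transit
            if (
                transits
                and transits[-1].border == z_now
                and i_entry - transits[-1].i_exit <= merge_frames
            ):
                prior = transits.pop()
                open_t = {
                    "border": z_now,
                    "t_entry": prior.t_entry,
                    "entry_dir": prior.entry_dir,
                    "i_entry": prior.i_entry,
                    "x_min": min(prior.x_min, x[j]),
                    "x_max": max(prior.x_max, x[j]),
                }
            else:
                open_t = {
                    "border": z_now,
                    "t_entry": t[j],
                    "entry_dir": entry_dir,
                    "i_entry": i_entry,
                    "x_min": x[j],
                    "x_max": x[j],
                }
    # a transit still open at epoch end is discarded
    return transits


def compute_choice_metrics(transits: list[Transit], fly_id: str = "") -> ChoiceMetrics:
    """ChI / PEDL / PELD from a fly's transit list (possibly empty)."""
    if not transits:
        return ChoiceMetrics(fly_id=fly_id)
    fly_id = fly_id or transits[0].fly_id
    n = len(transits)
    to_light = sum(1 for tr in transits if tr.exit_side == LIGHT)
    to_dark = n - to_light
    from_dark = [tr for tr in transits if tr.entry_side == DARK]
    from_light = [tr for tr in transits if tr.entry_side == LIGHT]
    m = ChoiceMetrics(
        fly_id=fly_id,
        chi=(to_light - to_dark) / n,
        n_transits=n,
        n_entries_from_dark=len(from_dark),
        n_entries_from_light=len(from_light),
    )
    if from_dark:
        m.pedl = sum(1 for tr in from_dark if tr.exit_side == LIGHT) / len(from_dark)
    if from_light:
        m.peld = sum(1 for tr in from_light if tr.exit_side == DARK) / len(from_light)
    return m


def pooled_choice_proportions(transit_lists: list[list[Transit]]) -> dict:
    """Transit-pooled ChI / PEDL / PELD across a group of flies.

    Pooling weights every transit equally (a ratio of total counts), which
    is the right estimator for recovering a common per-transit crossing
    probability: the unweighted mean of per-fly proportions overweights
    flies that crossed quickly and therefore accumulated few entries.
    """
    n = to_light = from_dark = from_dark_to_light = from_light = from_light_to_dark = 0
    for transits in transit_lists:
        for tr in transits:
            n += 1
            if tr.exit_side == LIGHT:
                to_light += 1
            if tr.entry_side == DARK:
                from_dark += 1
                if tr.exit_side == LIGHT:
                    from_dark_to_light += 1
            else:
                from_light += 1
                if tr.exit_side == DARK:
                    from_light_to_dark += 1
    return {
        "chi": (2.0 * to_light - n) / n if n else np.nan,
        "pedl": from_dark_to_light / from_dark if from_dark else np.nan,
        "peld": from_light_to_dark / from_light if from_light else np.nan,
        "n_transits": n,
        "n_entries_from_dark": from_dark,
        "n_entries_from_light": from_light,
    }


def choice_metrics_for_track(
    track: FlyTrack, arena: ArenaSpec, epoch: IlluminationEpoch
) -> ChoiceMetrics:
    """Convenience: annotate, segment and score one (already smoothed) track."""
    ann = annotate_zones(track, arena, epoch)
    return compute_choice_metrics(segment_transits(track, ann, arena), track.fly_id)


@dataclass
class AlignedTrajectory:
    """A transit's path re-referenced to zone entry.

    ``rel_time`` counts from the entry frame; ``signed_dist`` is the head's
    distance from the border with the dark side negative, so crossings run
    from about -3 mm toward positive values.
    """

    fly_id: str
    border: int
    rel_time: np.ndarray
    signed_dist: np.ndarray


def align_boundary_trajectories(
    transits: list[Transit],
    track: FlyTrack,
    arena: ArenaSpec,
    epoch: IlluminationEpoch,
    entry_side: str = DARK,
) -> list[AlignedTrajectory]:
    """Boundary-aligned trajectories for transits entered from one side.

    Only borders with a lit quadrant on exactly one side are informative;
    each selected transit's x is re-signed so its dark side is negative and
    time is re-zeroed at zone entry.
    """
    out = []
    for tr in transits:
        if tr.entry_side != entry_side:
            continue
        left = _side_state(tr.border, "left", epoch)
        right = _side_state(tr.border, "right", epoch)
        if left == right:
            continue  # dark epoch or uniform side: no light/dark axis
        sign = 1.0 if right == LIGHT else -1.0  # light side positive
        b = arena.border_positions[tr.border]
        sel = (track.frame_times >= tr.t_entry) & (track.frame_times <= tr.t_exit)
        sel &= track.valid_mask
        if not sel.any():
            continue
        tt = track.frame_times[sel]
        out.append(
            AlignedTrajectory(
                fly_id=tr.fly_id,
                border=tr.border,
                rel_time=tt - tr.t_entry,
                signed_dist=sign * (track.x[sel] - b),
            )
        )
    return out


def mean_aligned_trajectory(
    aligned: list[AlignedTrajectory], dt: float = 0.04, min_contributors: int = 3
) -> pd.DataFrame:
    """Pointwise mean aligned path over a common relative-time grid.

    Times are binned to the nominal frame interval; grid points with fewer
    than ``min_contributors`` trajectories are dropped.
    """
    if not aligned:
        return pd.DataFrame(columns=["rel_time", "mean_dist", "n"])
    rows = []
    for a in aligned:
        k = np.round(a.rel_time / dt).astype(int)
        rows.append(pd.DataFrame({"k": k, "d": a.signed_dist}))
    df = pd.concat(rows, ignore_index=True)
    g = df.groupby("k")["d"].agg(["mean", "count"]).reset_index()
    g = g[g["count"] >= min_contributors]
    return pd.DataFrame(
        {"rel_time": g["k"] * dt, "mean_dist": g["mean"], "n": g["count"]}
    )
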