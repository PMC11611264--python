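"""Per-frame zone annotation: quadrant, lit/unlit state, choice zone.

Annotation is a pure function of (x, arena, epoch).  Quadrants are
half-open intervals along x, so a frame exactly on a border belongs to the
right-hand quadrant; a frame is lit iff its quadrant is in the epoch's lit
set and the epoch is not dark; a frame is in choice zone ``k`` when it lies
within the choice half-width of border ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import ArenaSpec, IlluminationEpoch
from .track import FlyTrack

NO_ZONE = -1


@dataclass
class ZoneAnnotation:
    """Frame-aligned annotation for one fly during one epoch.

    Arrays cover exactly the frames inside the epoch (``frame_index`` maps
    back into the track); ``choice_zone`` holds the border index or
    ``NO_ZONE``.
    """

    fly_id: str
    epoch: IlluminationEpoch
    frame_index: np.ndarray
    times: np.ndarray
    lit: np.ndarray
    quadrant: np.ndarray
    choice_zone: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


def quadrant_index(x: np.ndarray, arena: ArenaSpec) -> np.ndarray:
    """Half-open interval convention: x on a border -> right-hand quadrant."""
    borders = np.asarray(arena.border_positions)
    return np.searchsorted(borders, np.asarray(x, dtype=float), side="right")


def lit_state(x: np.ndarray, arena: ArenaSpec, epoch: IlluminationEpoch) -> np.ndarray:
    """Binary lit/unlit per frame by nominal border position."""
    if epoch.is_dark:
        return np.zeros(np.shape(x), dtype=bool)
    q = quadrant_index(x, arena)
    lit = np.zeros(q.shape, dtype=bool)
    for qi in epoch.lit_quadrants:
        lit |= q == qi
    return lit


def choice_zone_index(x: np.ndarray, arena: ArenaSpec) -> np.ndarray:
    """Border index of the containing choice zone, or NO_ZONE.

    Zones never overlap (ArenaSpec invariant), so the nearest border is
    unambiguous.
    """
    x = np.asarray(x, dtype=float)
    borders = np.asarray(arena.border_positions)
    dist = np.abs(x[:, None] - borders[None, :])
    nearest = np.argmin(dist, axis=1)
    inside = dist[np.arange(len(x)), nearest] <= arena.choice_halfwidth
    return np.where(inside, nearest, NO_ZONE)


def annotate_zones(
    track: FlyTrack, arena: ArenaSpec, epoch: IlluminationEpoch
) -> ZoneAnnotation:
    """Annotate the frames of ``track`` falling inside ``epoch``.

    Frames outside the epoch are excluded (not an error).
    """
    sel = np.flatnonzero(track.window(epoch.start, epoch.end))
    x = track.x[sel]
    return ZoneAnnotation(
        fly_id=track.fly_id,
        epoch=epoch,
        frame_index=sel,
        times=track.frame_times[sel],
        lit=lit_state(x, arena, epoch),
        quadrant=quadrant_index(x, arena),
        choice_zone=choice_zone_index(x, arena),
        valid=track.valid_mask[sel],
    )
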