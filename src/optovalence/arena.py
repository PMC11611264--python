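"""Arena geometry and illumination schedules.

The assay arena is a 55 x 4 mm stadium ("discorectangle") whose long axis is
divided into four equal quadrants by three light/dark borders.  During a lit
epoch, alternating quadrants are illuminated to produce a banded
light-dark-light-dark pattern; a choice zone extends 3 mm to either side of
each border.  The physical light border is not perfectly sharp: a finite
intensity gradient (mean width 0.67 mm) separates lit from unlit regions,
which the simulator reproduces.  Occupancy scoring, however, is binary by
nominal border position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class LightColor(str, Enum):
    RED = "red"
    GREEN = "green"
    DARK = "dark"


def _default_borders(length: float) -> tuple[float, ...]:
    return (length / 4.0, length / 2.0, 3.0 * length / 4.0)


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of one stadium arena.

    Parameters
    ----------
    length, width:
        Interior dimensions in mm; x runs along the long axis with the
        origin at the left end.
    border_positions:
        Positions of the light/dark borders along x, strictly increasing
        and strictly interior.  Quadrant ``i`` is the half-open interval
        ``[b[i-1], b[i])`` (with the arena ends closing the outer
        quadrants), so a fly exactly on a border belongs to the right-hand
        quadrant.
    choice_halfwidth:
        Half-width in mm of the choice zone centred on each border.
    gradient_width:
        Width in mm of the light-intensity gradient at each border; used
        by the simulator's speed rule only, never by occupancy scoring.
    """

    length: float = 55.0
    width: float = 4.0
    border_positions: tuple[float, ...] = ()
    choice_halfwidth: float = 3.0
    gradient_width: float = 0.67

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("arena dimensions must be positive")
        if not self.border_positions:
            object.__setattr__(
                self, "border_positions", _default_borders(self.length)
            )
        borders = tuple(float(b) for b in self.border_positions)
        object.__setattr__(self, "border_positions", borders)
        if any(b2 <= b1 for b1, b2 in zip(borders, borders[1:])):
            raise ValueError("border positions must be strictly increasing")
        if borders[0] <= 0 or borders[-1] >= self.length:
            raise ValueError("borders must lie strictly inside the arena")
        if self.choice_halfwidth <= 0:
            raise ValueError("choice_halfwidth must be positive")
        h = self.choice_halfwidth
        if borders[0] - h < 0 or borders[-1] + h > self.length:
            raise ValueError("choice zones must lie inside the arena")
        if any(b2 - b1 <= 2 * h for b1, b2 in zip(borders, borders[1:])):
            raise ValueError("choice zones must not overlap")
        if self.gradient_width < 0:
            raise ValueError("gradient_width must be non-negative")

    @property
    def n_quadrants(self) -> int:
        return len(self.border_positions) + 1

    def quadrant_of(self, x: float) -> int:
        """0-based quadrant index; half-open convention at borders."""
        q = 0
        for b in self.border_positions:
            if x >= b:
                q += 1
        return q


@dataclass(frozen=True)
class IlluminationEpoch:
    """One epoch of the illumination schedule.

    ``lit_quadrants`` lists the quadrant indices illuminated during the
    epoch; the published protocol lights quadrants 0 and 2 for 60 s.  A
    dark epoch has color ``dark``, intensity 0 and an empty lit set.
    """

    start: float
    end: float
    intensity: float = 0.0
    color: LightColor = LightColor.DARK
    lit_quadrants: frozenset[int] = field(default_factory=frozenset)
    label: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("epoch end must exceed start")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        color = LightColor(self.color)
        object.__setattr__(self, "color", color)
        object.__setattr__(self, "lit_quadrants", frozenset(self.lit_quadrants))
        if (color is LightColor.DARK) != (len(self.lit_quadrants) == 0):
            raise ValueError("dark epochs and only dark epochs have an empty lit set")

    @property
    def is_dark(self) -> bool:
        return self.color is LightColor.DARK

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_schedule(schedule: Sequence[IlluminationEpoch]) -> None:
    """Require epochs to be time-ordered and non-overlapping."""
    if not schedule:
        raise ValueError("schedule must contain at least one epoch")
    for a, b in zip(schedule, schedule[1:]):
        if b.start < a.end:
            raise ValueError(
                f"epochs overlap or are out of order: {a.label or a.start} / "
                f"{b.label or b.start}"
            )


# Published stimulus intensities, uW/mm^2.
RED_INTENSITIES = (1.3, 5.0, 22.0, 70.0)
GREEN_INTENSITIES = (1.6, 7.0, 28.0, 92.0)


def standard_schedule(
    intensities: Sequence[float] = RED_INTENSITIES,
    color: LightColor = LightColor.RED,
    epoch_s: float = 60.0,
    lit_quadrants: Sequence[int] = (0, 2),
) -> list[IlluminationEpoch]:
    """Dark baseline followed by alternating dark / lit 60 s epochs.

    Mirrors the published protocol: each test intensity is presented for
    one epoch, preceded by a dark epoch, with the banded pattern produced
    by lighting quadrants 0 and 2.
    """
    schedule = [
        IlluminationEpoch(0.0, epoch_s, 0.0, LightColor.DARK, frozenset(), "dark0")
    ]
    t = epoch_s
    for i, level in enumerate(intensities):
        schedule.append(
            IlluminationEpoch(
                t, t + epoch_s, level, color, frozenset(lit_quadrants), f"lit{i}"
            )
        )
        t += epoch_s
        if i < len(intensities) - 1:
            schedule.append(
                IlluminationEpoch(
                    t, t + epoch_s, 0.0, LightColor.DARK, frozenset(), f"dark{i + 1}"
                )
            )
            t += epoch_s
    return schedule
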