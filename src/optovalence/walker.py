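"""Agent-based simulator of fly walking in the stadium arena.

The walk is quasi-1-D: motion is dominantly along the long (x) axis with
bounded lateral jitter, since every published metric depends only on x.
Two independently tunable mechanisms generate valence, mirroring the two
hypothesised locomotor modes:

* **Speed modulation** ("DAN-like"): while in lit territory the walking
  speed is multiplied by ``light_speed_multiplier`` (m); log2(m) is the
  per-fly target speed ratio.  A fly that is slower in the light (m < 1)
  accumulates time there, yielding positive preference without any
  directed choice.
* **Boundary turning bias** ("MBON-like"): on each choice-zone entry the
  transit outcome (cross vs reverse) is drawn once from the
  side-appropriate crossing probability, making PEDL and PELD directly
  parameterisable.

Additional realism: a two-state pause process, spontaneous heading
reversals, reflecting arena ends, multiplicative speed noise, and a finite
light gradient at borders — the speed rule interpolates the multiplier
across the gradient band, while the behavioural transit draw uses the
nominal border, matching the binary occupancy convention of the analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .arena import ArenaSpec, IlluminationEpoch, validate_schedule
from .track import ExperimentRecord, FlyTrack

FPS = 25.0

#: Duration of a U-turn arc, s.  Walking flies reverse direction by
#: swinging through a tight arc over a few hundred milliseconds rather
#: than stopping dead; the head keeps moving throughout.
TURN_DURATION_S = 0.32

#: Debug hook: when set to a list, every choice-zone outcome draw is
#: appended as (fly_id, frame, entry_side_lit, drawn_crossing).
_TRACE: list | None = None


@dataclass(frozen=True)
class WalkerParams:
    """Parameters of one simulated fly genotype.

    Units: speeds mm/s, rates events/s, durations s.
    ``light_speed_multiplier`` m scales walking speed in lit territory
    (log2 m is the target per-fly LSR); the two ``p_cross`` values are the
    target PEDL and PELD.  ``lateral_jitter_sd`` is the SD of the lateral
    (y) displacement per step *at base speed*; lateral wobble is part of
    the gait, so it scales with the instantaneous step length and vanishes
    while paused — a speed-independent jitter would inflate slow speeds
    relative to fast ones and distort the measured speed ratio.
    """

    base_speed: float = 8.0
    speed_noise_cv: float = 0.3
    light_speed_multiplier: float = 1.0
    pause_rate: float = 0.2
    pause_duration_mean: float = 1.0
    heading_persistence: float = 0.1
    p_cross_dark_to_light: float = 0.5
    p_cross_light_to_dark: float = 0.5
    lateral_jitter_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.base_speed <= 0 or self.light_speed_multiplier <= 0:
            raise ValueError("speeds and the light multiplier must be positive")
        if self.pause_rate < 0 or self.pause_duration_mean <= 0:
            raise ValueError("invalid pause parameters")
        for p in (self.p_cross_dark_to_light, self.p_cross_light_to_dark):
            if not 0.0 <= p <= 1.0:
                raise ValueError("crossing probabilities must lie in [0, 1]")
        if self.speed_noise_cv < 0 or self.lateral_jitter_sd < 0:
            raise ValueError("noise terms must be non-negative")
        if self.heading_persistence < 0:
            raise ValueError("heading_persistence must be non-negative")


@dataclass
class GroundTruth:
    """Expected metric values implied by a parameter set."""

    expected_lsr: float
    expected_pedl: float
    expected_peld: float
    expected_pi_sign: int  # -1, 0, +1
    provenance: str  # "analytic" or "monte-carlo"


def _epoch_at(schedule: Sequence[IlluminationEpoch], t: float) -> IlluminationEpoch | None:
    for ep in schedule:
        if ep.start <= t < ep.end:
            return ep
    return None


def simulate_fly(
    params: WalkerParams,
    arena: ArenaSpec,
    schedule: Sequence[IlluminationEpoch],
    seed,
    fly_id: str = "fly0",
) -> FlyTrack:
    """Simulate one fly at 25 frames/s across the whole schedule.

    ``seed`` may be an int or a ``numpy.random.SeedSequence``; identical
    (params, seed) always yield an identical track.
    """
    validate_schedule(schedule)
    rng = np.random.default_rng(seed)
    t0, t_end = schedule[0].start, schedule[-1].end
    dt = 1.0 / FPS
    n = int(round((t_end - t0) * FPS))
    times = t0 + np.arange(n) * dt

    # pre-drawn randomness (one array per per-frame decision)
    sigma = math.sqrt(math.log(1.0 + params.speed_noise_cv**2))
    noise = rng.lognormal(-0.5 * sigma * sigma, sigma, n)
    u_pause = rng.random(n)
    u_rev = rng.random(n)
    y_step = rng.normal(0.0, params.lateral_jitter_sd, n)
    u_transit = rng.random(n)
    u_depth = rng.random(n)
    x0 = rng.uniform(0.0, arena.length)
    y0 = rng.uniform(0.0, arena.width)
    heading = 1.0 if rng.random() < 0.5 else -1.0

    borders = arena.border_positions
    half = arena.choice_halfwidth
    grad = arena.gradient_width
    m = params.light_speed_multiplier
    p_pause_in = params.pause_rate * dt
    p_pause_out = dt / params.pause_duration_mean
    p_rev = params.heading_persistence * dt

    # per-frame epoch lookup (epoch boundaries are far sparser than frames)
    epoch_of_frame: list[IlluminationEpoch | None] = [None] * n
    for ep in schedule:
        i0 = max(0, int(math.ceil((ep.start - t0) * FPS - 1e-9)))
        i1 = min(n, int(math.ceil((ep.end - t0) * FPS - 1e-9)))
        for i in range(i0, i1):
            epoch_of_frame[i] = ep

    def zone_of(x: float) -> int:
        for k, b in enumerate(borders):
            if abs(x - b) <= half:
                return k
        return -1

    def lit_fraction(x: float, ep: IlluminationEpoch | None) -> float:
        """Continuous lit fraction at x: 0/1 away from borders, linear
        interpolation across the gradient band."""
        if ep is None or ep.is_dark:
            return 0.0
        lit_q = ep.lit_quadrants
        q = 0
        for b in borders:
            if x >= b:
                q += 1
        nominal = 1.0 if q in lit_q else 0.0
        if grad <= 0:
            return nominal
        for k, b in enumerate(borders):
            d = x - b
            if abs(d) < 0.5 * grad:
                left = 1.0 if k in lit_q else 0.0
                right = 1.0 if (k + 1) in lit_q else 0.0
                frac = (d + 0.5 * grad) / grad
                return left * (1.0 - frac) + right * frac
        return nominal

    xs = np.empty(n)
    ys = np.empty(n)
    x, y = x0, y0
    paused = False
    cur_zone = zone_of(x)
    steer = 0.0  # nonzero while a transit outcome is being executed
    turn_at = None  # turn-around point for a drawn reversal
    # turning state: heading reversals are executed as constant-speed
    # semicircular arcs (the head keeps moving while the body swings
    # around), not instantaneous corners
    k_turn = max(2, int(round(TURN_DURATION_S / dt)))
    turn_step = -1  # -1: not turning; else frames completed of the arc
    turn_dir_x = 1.0
    turn_dir_y = 1.0
    base = params.base_speed
    length = arena.length
    width = arena.width

    def start_turn() -> None:
        nonlocal turn_step, turn_dir_x, turn_dir_y
        turn_step = 0
        turn_dir_x = heading
        turn_dir_y = 1.0 if y < 0.5 * width else -1.0

    for i in range(n):
        ep = epoch_of_frame[i]
        if paused:
            if u_pause[i] < p_pause_out:
                paused = False
        else:
            if u_pause[i] < p_pause_in:
                paused = True
        if steer == 0.0 and turn_step < 0 and u_rev[i] < p_rev:
            start_turn()
        v = 0.0
        if not paused:
            lf = lit_fraction(x, ep)
            v = base * (1.0 + (m - 1.0) * lf) * noise[i]
            if turn_step >= 0:
                theta = math.pi * (turn_step + 0.5) / k_turn
                x = x + v * dt * math.cos(theta) * turn_dir_x
                y = y + v * dt * math.sin(theta) * turn_dir_y
                if x < 0.0:
                    x = 0.0
                elif x > length:
                    x = length
                turn_step += 1
                if turn_step >= k_turn:
                    turn_step = -1
                    heading = -turn_dir_x
            else:
                if steer != 0.0 and turn_at is not None:
                    # drawn reversal: proceed to the turn point, then swing
                    if (steer > 0 and x >= turn_at) or (steer < 0 and x <= turn_at):
                        heading = 1.0 if steer > 0 else -1.0
                        steer = -steer
                        turn_at = None
                        start_turn()
                    else:
                        heading = 1.0 if steer > 0 else -1.0
                elif steer != 0.0:
                    heading = 1.0 if steer > 0 else -1.0
                if turn_step < 0:
                    x = x + heading * v * dt
                    y = y + y_step[i] * (v / base)
            if turn_step < 0 and (
                (x <= 0.0 and heading < 0) or (x >= length and heading > 0)
            ):
                # arena end: clamp against the wall and swing around
                x = min(max(x, 0.0), length)
                start_turn()  # heading still presses into the wall
        if y < 0.0:
            y = -y
        elif y > width:
            y = 2.0 * width - y

        z = zone_of(x)
        if z != cur_zone:
            if cur_zone != -1:  # left a zone: transit over
                steer = 0.0
                turn_at = None
            if z != -1 and ep is not None and not ep.is_dark:
                # zone entry: draw the transit outcome once
                b = borders[z]
                from_left = x < b if cur_zone == -1 else heading > 0
                side_q = z if from_left else z + 1
                side_lit = side_q in ep.lit_quadrants
                p_cross = (
                    params.p_cross_light_to_dark
                    if side_lit
                    else params.p_cross_dark_to_light
                )
                inward = 1.0 if from_left else -1.0
                turn_step = -1  # the draw commits the fly: cancel any arc
                if _TRACE is not None:
                    _TRACE.append((fly_id, i, side_lit, bool(u_transit[i] < p_cross)))
                if u_transit[i] < p_cross:
                    steer = inward  # carry on through to the far side
                    turn_at = None
                else:
                    # the fly decides at the light edge it can sense: it
                    # walks into the gradient band (or just past it) before
                    # swinging around
                    steer = inward
                    turn_at = b + inward * (1.5 * u_depth[i] - 0.5)
            cur_zone = z
        xs[i] = x
        ys[i] = y

    return FlyTrack(fly_id=fly_id, frame_times=times, x=xs, y=ys)


def simulate_group(
    params: WalkerParams,
    arena: ArenaSpec,
    schedule: Sequence[IlluminationEpoch],
    n_flies: int,
    seed,
    group_label: str,
    metadata: dict | None = None,
) -> ExperimentRecord:
    """Simulate ``n_flies`` independent flies sharing one parameter set.

    Per-fly streams are spawned from one root seed by counter, so adding a
    fly never perturbs the others.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = root.spawn(n_flies)
    tracks = [
        simulate_fly(params, arena, schedule, child, fly_id=f"{group_label}_{i:03d}")
        for i, child in enumerate(children)
    ]
    meta = dict(metadata or {})
    meta.setdefault("params", params)
    return ExperimentRecord(
        tracks=tracks,
        arena=arena,
        schedule=list(schedule),
        group_label=group_label,
        metadata=meta,
    )


def simulate_experiment(
    test_params: WalkerParams,
    control_params: WalkerParams,
    n_per_group: int,
    arena: ArenaSpec,
    schedule: Sequence[IlluminationEpoch],
    seed,
) -> dict[str, ExperimentRecord]:
    """Three-group design: one test and two genetically distinct controls.

    Both control groups draw from ``control_params`` with distinct
    sub-seeds, emulating the driver-control / responder-control pair.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_test, s_c1, s_c2 = root.spawn(3)
    return {
        "test": simulate_group(test_params, arena, schedule, n_per_group, s_test, "test"),
        "driver-control": simulate_group(
            control_params, arena, schedule, n_per_group, s_c1, "driver-control"
        ),
        "responder-control": simulate_group(
            control_params, arena, schedule, n_per_group, s_c2, "responder-control"
        ),
    }


def ground_truth(
    params: WalkerParams,
    arena: ArenaSpec | None = None,
    schedule: Sequence[IlluminationEpoch] | None = None,
    n_mc: int = 60,
    seed: int = 12345,
) -> GroundTruth:
    """Expected metrics for a parameter set.

    The expected LSR is analytic (log2 m) and PEDL/PELD pass through.  The
    preference sign follows from the parameter asymmetries when the two
    mechanisms agree; when they conflict a small Monte-Carlo simulation
    decides (sign of the mean PI when it clears 2 SEM, else 0).
    """
    m = params.light_speed_multiplier
    sign_speed = int(np.sign(1.0 - m))
    sign_choice = int(
        np.sign(params.p_cross_dark_to_light - params.p_cross_light_to_dark)
    )
    if sign_speed == sign_choice or sign_choice == 0 or sign_speed == 0:
        pi_sign = sign_speed if sign_speed != 0 else sign_choice
        provenance = "analytic"
    else:
        from .metrics import summarize_group  # deferred: avoids import cycle

        arena = arena or ArenaSpec()
        if schedule is None:
            lit = IlluminationEpoch(0.0, 60.0, 22.0, "red", frozenset({0, 2}), "lit")
            schedule = [lit]
        rec = simulate_group(params, arena, schedule, n_mc, seed, "mc")
        lit_epochs = [ep for ep in schedule if not ep.is_dark]
        table = summarize_group(rec, epochs=lit_epochs[:1])
        pis = table["pi"].dropna().to_numpy()
        mean, sem = float(np.mean(pis)), float(np.std(pis, ddof=1) / np.sqrt(len(pis)))
        pi_sign = int(np.sign(mean)) if abs(mean) > 2 * sem else 0
        provenance = "monte-carlo"
    return GroundTruth(
        expected_lsr=float(np.log2(m)),
        expected_pedl=params.p_cross_dark_to_light,
        expected_peld=params.p_cross_light_to_dark,
        expected_pi_sign=pi_sign,
        provenance=provenance,
    )
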