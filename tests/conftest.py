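import numpy as np
import pytest

from optovalence import ArenaSpec, FlyTrack, IlluminationEpoch

FPS = 25.0
DT = 1.0 / FPS


@pytest.fixture
def arena():
    return ArenaSpec()


@pytest.fixture
def lit_epoch():
    return IlluminationEpoch(0.0, 60.0, 22.0, "red", frozenset({0, 2}), "lit")


@pytest.fixture
def dark_epoch():
    return IlluminationEpoch(0.0, 60.0, 0.0, "dark", frozenset(), "dark")


def track_from_x(x, fly_id="f0", t0=0.0, y=2.0, valid=None):
    """FlyTrack from an x series sampled at 25 fps."""
    x = np.asarray(x, float)
    t = t0 + np.arange(len(x)) * DT
    yv = np.full(len(x), y) if np.isscalar(y) else np.asarray(y, float)
    return FlyTrack(fly_id=fly_id, frame_times=t, x=x, y=yv, valid_mask=valid)


def piecewise_track(segments, x0, fly_id="f0", t0=0.0, y=2.0):
    """Track built from (duration_s, velocity_mm_s) segments at 25 fps."""
    xs = [x0]
    for dur, v in segments:
        n = int(round(dur * FPS))
        for _ in range(n):
            xs.append(xs[-1] + v * DT)
    return track_from_x(np.array(xs), fly_id=fly_id, t0=t0, y=y)


def zigzag_segments(total_s, speed, lo, hi, x0, direction=1):
    """(duration, velocity) segments bouncing between lo and hi."""
    segs = []
    x, d, remaining = x0, direction, total_s
    while remaining > 1e-9:
        target = hi if d > 0 else lo
        dur = min(abs(target - x) / speed, remaining)
        segs.append((dur, d * speed))
        x += d * speed * dur
        remaining -= dur
        d = -d
    return segs
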