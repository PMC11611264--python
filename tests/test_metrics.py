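"""Per-fly preference (PI), speed ratio (LSR) and conditioning scores."""

import numpy as np
import pytest

from optovalence import (
    IlluminationEpoch,
    annotate_zones,
    compute_conditioning_pi,
    compute_lsr,
    compute_pi,
    simulate_group,
    summarize_group,
)
from optovalence.metrics import (
    NO_MOVEMENT,
    SINGLE_ZONE,
    _frame_dts,
)

from conftest import DT, piecewise_track, track_from_x, zigzag_segments


def pi_of(track, arena, epoch, window_s=30.0):
    ann = annotate_zones(track, arena, epoch)
    return compute_pi(track, ann, window_s)


def lsr_of(track, arena, epoch, window_s=30.0, **kw):
    ann = annotate_zones(track, arena, epoch)
    m = compute_pi(track, ann, window_s)
    return compute_lsr(track, ann, window_s, metrics=m, arena=arena, **kw)


class TestPreferenceIndex:
    def test_all_window_time_lit_gives_plus_one(self, arena, lit_epoch):
        # moving inside the lit quadrant 0 interior the whole epoch
        tr = piecewise_track(zigzag_segments(60.0, 2.0, 4.0, 10.0, 5.0), 5.0)
        m = pi_of(tr, arena, lit_epoch)
        assert m.pi == 1.0

    def test_partial_occupancy_matches_dt_sum(self, arena, lit_epoch):
        # last 30 s: 18 s in lit quadrant 0, then 12 s in dark quadrant 1
        # (teleport step keeps occupancy accounting trivial)
        n18, n12 = int(18 * 25), int(12 * 25)
        x = np.concatenate([
            np.full(int(30 * 25), 20.0),  # first 30 s, dark (not scored)
            np.full(n18, 6.0),
            np.full(n12, 20.0),
        ])
        m = pi_of(track_from_x(x), arena, lit_epoch)
        assert m.pi == pytest.approx((18.0 - 12.0) / 30.0, abs=2e-3)
        assert m.pi_source == "measured"

    def test_dark_confined_moving_fly_gets_extreme_minus_one(self, arena, lit_epoch):
        # stays in dark quadrant 1 interior all epoch, path length >> 2 mm
        tr = piecewise_track(zigzag_segments(60.0, 2.0, 18.0, 24.0, 20.0), 20.0)
        m = pi_of(tr, arena, lit_epoch)
        assert m.pi == -1.0
        assert m.pi_source == "extreme_assigned"

    def test_lit_confined_moving_fly_gets_extreme_plus_one(self, arena, lit_epoch):
        tr = piecewise_track(zigzag_segments(60.0, 2.0, 4.0, 10.0, 5.0), 5.0)
        m = pi_of(tr, arena, lit_epoch)
        assert m.pi == 1.0 and m.pi_source == "extreme_assigned"

    def test_no_valid_frames_is_censored_not_an_exception(self, arena, lit_epoch):
        tr = track_from_x(np.full(100, 10.0), valid=np.zeros(100, bool))
        m = pi_of(tr, arena, lit_epoch)
        assert m.pi_censored and m.censor_flags

    def test_time_accounting_covers_window(self, arena, lit_epoch):
        tr = piecewise_track(zigzag_segments(60.0, 5.0, 5.0, 50.0, 10.0), 10.0)
        m = pi_of(tr, arena, lit_epoch)
        assert m.time_in_light + m.time_in_dark == pytest.approx(30.0, abs=0.2)


class TestSpeedRatio:
    def test_equal_speeds_give_zero(self, arena, lit_epoch):
        tr = piecewise_track(zigzag_segments(60.0, 2.0, 5.0, 50.0, 10.0), 10.0)
        m = lsr_of(tr, arena, lit_epoch, window_s=60.0)
        assert m.lsr == pytest.approx(0.0, abs=0.05)

    def test_twice_as_fast_in_light_gives_lsr_one(self, arena, lit_epoch):
        # 1 mm/s cruise in the dark quadrant-1 interior, one crossing,
        # then 2 mm/s zigzag in the lit quadrant-2 interior
        segs = [(9.5, 1.0)]  # 18 -> 27.5 crosses the border at t = 9.5
        segs += [(1.5, 2.0)]  # 27.5 -> 30.5 through the choice zone
        segs += zigzag_segments(49.0, 2.0, 31.0, 38.0, 30.5)
        tr = piecewise_track(segs, 18.0)
        m = lsr_of(tr, arena, lit_epoch, window_s=60.0)
        assert m.lsr == pytest.approx(1.0, abs=1e-6)
        assert m.mean_speed_light == pytest.approx(2.0, abs=1e-6)
        assert m.mean_speed_dark == pytest.approx(1.0, abs=1e-6)

    def test_single_zone_fly_censored_for_lsr_but_not_pi(self, arena, lit_epoch):
        tr = piecewise_track(zigzag_segments(60.0, 2.0, 18.0, 24.0, 20.0), 20.0)
        m = lsr_of(tr, arena, lit_epoch)
        assert m.lsr_censored and SINGLE_ZONE in m.censor_flags
        assert m.pi == -1.0  # PI still defined

    def test_stationary_fly_censored_no_movement(self, arena, lit_epoch):
        m = lsr_of(track_from_x(np.full(1500, 20.0)), arena, lit_epoch)
        assert m.lsr_censored and NO_MOVEMENT in m.censor_flags

    def test_scale_invariance_of_pi_and_lsr(self, arena, lit_epoch):
        segs = [(9.5, 1.0), (1.5, 2.0)] + zigzag_segments(49.0, 2.0, 31.0, 38.0, 30.5)
        slow = piecewise_track(segs, 18.0)
        fast = piecewise_track([(d / 2, v * 2) for d, v in segs], 18.0)
        # doubling all speeds (halving durations) leaves LSR unchanged
        m_slow = lsr_of(slow, arena, lit_epoch, window_s=60.0)
        m_fast = lsr_of(fast, arena, lit_epoch, window_s=60.0)
        assert m_fast.lsr == pytest.approx(m_slow.lsr, abs=1e-6)


class TestCensoringHierarchy:
    def test_each_rule_only_removes_flies(self, arena):
        sched = [
            IlluminationEpoch(0, 60, 0, "dark", frozenset(), "dark0"),
            IlluminationEpoch(60, 120, 22, "red", frozenset({0, 2}), "lit0"),
        ]
        from optovalence import WalkerParams

        rec = simulate_group(
            WalkerParams(pause_rate=0.6, pause_duration_mean=4.0),
            arena, sched, 30, 424242, "g",
        )
        tab = summarize_group(rec, epochs=[sched[1]])
        n_pi = tab["pi"].notna().sum()
        n_lsr = tab["lsr"].notna().sum()
        n_chi = tab["chi"].notna().sum()
        assert n_pi >= n_lsr and n_pi >= n_chi

    def test_all_single_zone_group_keeps_pi_column(self, arena, lit_epoch):
        from optovalence.track import ExperimentRecord

        tracks = [
            piecewise_track(zigzag_segments(60.0, 2.0, 18.0, 24.0, 20.0), 20.0,
                            fly_id=f"f{i}")
            for i in range(4)
        ]
        rec = ExperimentRecord(tracks, arena, [lit_epoch], "g")
        tab = summarize_group(rec, smooth=False)
        assert tab["lsr"].isna().all()
        assert tab["pi"].notna().all()

    def test_flags_survive_table_round_trip(self, tmp_path, arena, lit_epoch):
        from optovalence.track import ExperimentRecord
        import pandas as pd

        tracks = [piecewise_track(zigzag_segments(60.0, 2.0, 18.0, 24.0, 20.0),
                                  20.0, fly_id="f0")]
        rec = ExperimentRecord(tracks, arena, [lit_epoch], "g")
        tab = summarize_group(rec, smooth=False)
        p = tmp_path / "m.csv"
        tab.to_csv(p, index=False)
        back = pd.read_csv(p)
        assert back.loc[0, "censor_flags"] == tab.loc[0, "censor_flags"]


class TestConditioning:
    def _phase(self, frac_plus, side, n_flies=4):
        # flies split their last-30 s occupancy frac/1-frac across the
        # midline (25 mm) of the arena; CS+ on `side`
        n = int(30 * 25)
        tracks = []
        for i in range(n_flies):
            k = int(round(frac_plus * n))
            plus_x, minus_x = (40.0, 10.0) if side == "right" else (10.0, 40.0)
            x = np.concatenate([np.full(k, plus_x), np.full(n - k, minus_x)])
            tracks.append(track_from_x(x, fly_id=f"f{i}"))
        return tracks

    def test_halves_average_into_full_pi(self, arena):
        a = self._phase(0.75, "left")   # half PI = +0.5
        b = self._phase(0.65, "right")  # half PI = +0.3
        res = compute_conditioning_pi(a, b, "left", midline=25.0)
        assert res.half_pi_a == pytest.approx(0.5, abs=5e-3)
        assert res.half_pi_b == pytest.approx(0.3, abs=5e-3)
        assert res.full_pi == pytest.approx(0.4, abs=5e-3)

    def test_side_bias_cancels(self, arena):
        # a pure side preference: +0.6 in one phase, -0.6 in the swapped one
        a = self._phase(0.8, "left")
        b = self._phase(0.2, "right")
        res = compute_conditioning_pi(a, b, "left", midline=25.0)
        assert res.full_pi == pytest.approx(0.0, abs=5e-3)

    def test_biased_cohort_scores_expected_full_pi(self, arena):
        # 70/30 occupancy toward CS+ in both phases -> full PI ~ +0.4
        a = self._phase(0.7, "right")
        b = self._phase(0.7, "left")
        res = compute_conditioning_pi(a, b, "right", midline=25.0)
        assert res.full_pi == pytest.approx(0.4, abs=5e-3)

    def test_missing_phase_is_an_error(self):
        with pytest.raises(ValueError):
            compute_conditioning_pi([], [], "left", midline=25.0)


def test_frame_dts_caps_long_gaps():
    t = np.array([0.0, 0.04, 0.08, 1.0, 1.04])
    dts = _frame_dts(t, 0.04)
    assert dts[2] == pytest.approx(0.04)  # 0.92 s gap credited one frame
    assert dts[-1] == pytest.approx(0.04)
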