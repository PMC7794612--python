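"""The six evaluation indices: velocity, stopping probability, F_v, windows."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ventrack as vt
from ventrack.indices import INDEX_COLUMNS, stopping_probability
from ventrack.position import PositionTrack
from ventrack.signal_processing import PeakMap


def _track(xy, f_m=33.0):
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    return PositionTrack(t=np.arange(n) / f_m, xy=xy, xy_raw=xy,
                         degenerate=np.zeros(n, dtype=bool))


class TestVelocity:
    def test_constant_position_zero_speed(self):
        vel = vt.differentiate_positions(_track(np.tile([10.0, 20.0], (200, 1))))
        assert np.allclose(vel.speed, 0.0, atol=1e-9)

    def test_linear_ramp_recovers_speed(self):
        t = np.arange(400) / 33.0
        xy = np.column_stack([10.0 * t, np.zeros_like(t)])
        vel = vt.differentiate_positions(_track(xy))
        mid = vel.v[100:-100, 0]
        assert np.allclose(mid, 10.0, rtol=0.02)

    def test_time_reversal_negates_velocity(self):
        # smooth in-band trajectory; edge ticks excluded (zero-phase filter
        # edge handling is not exactly reversal-symmetric on broadband input)
        t = np.arange(600) / 33.0
        xy = np.column_stack([30 * np.sin(2 * np.pi * 0.3 * t),
                              20 * np.cos(2 * np.pi * 0.5 * t + 1.0)])
        fwd = vt.differentiate_positions(_track(xy))
        bwd = vt.differentiate_positions(_track(xy[::-1]))
        np.testing.assert_allclose(bwd.v[100:-100], -fwd.v[::-1][100:-100],
                                   atol=1e-3)

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            vt.differentiate_positions(_track([[0.0, 0.0], [1.0, 1.0]]))


class TestStoppingProbability:
    def test_extremes(self):
        assert stopping_probability(np.zeros(165), v_stop=3.0) == 100.0
        assert stopping_probability(np.full(165, 50.0), v_stop=3.0) == 0.0

    def test_hand_counted_fraction(self):
        speeds = np.full(165, 10.0)
        speeds[:33] = 1.0
        assert stopping_probability(speeds, v_stop=3.0) == pytest.approx(20.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            stopping_probability(np.array([]), v_stop=3.0)

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_brute_force_per_tick_loop(self, seed):
        rng = np.random.default_rng(seed)
        speeds = rng.uniform(0.0, 10.0, size=rng.integers(1, 400))
        v_stop = rng.uniform(0.5, 8.0)
        brute = 100.0 * sum(1 for s in speeds if s < v_stop) / len(speeds)
        assert stopping_probability(speeds, v_stop) == brute


class TestVentilatoryFrequency:
    def _two_electrode_arena(self):
        return vt.ArenaGeometry(width_x=100.0, width_y=10.0,
                                electrode_positions=np.array([[20.0, 5.0], [80.0, 5.0]]),
                                pitch=60.0, grid_shape=None)

    def _maps(self, n, freqs=(2.0, 8.0)):
        return [PeakMap(t=i / 33.0, peak_freq=np.array(freqs),
                        peak_power=np.ones(2), ar_order=10) for i in range(n)]

    def test_nearest_electrode_lookup(self):
        arena = self._two_electrode_arena()
        track = _track(np.tile([25.0, 5.0], (5, 1)))
        fv = vt.ventilatory_frequency_at(track, self._maps(5), arena=arena)
        assert np.all(fv == 2.0)

    def test_crossing_switches_exactly_once(self):
        arena = self._two_electrode_arena()
        xs = np.linspace(20.0, 80.0, 33)
        track = _track(np.column_stack([xs, np.full(33, 5.0)]))
        fv = vt.ventilatory_frequency_at(track, self._maps(33), arena=arena)
        assert (np.diff(fv) != 0).sum() == 1

    def test_degenerate_ticks_carry_forward(self):
        arena = self._two_electrode_arena()
        xy = np.vstack([np.tile([25.0, 5.0], (3, 1)), np.tile([75.0, 5.0], (3, 1))])
        track = _track(xy)
        track.degenerate[3:] = True
        fv = vt.ventilatory_frequency_at(track, self._maps(6), arena=arena)
        assert np.all(fv == 2.0)

    def test_grid_mismatch_rejected(self):
        arena = self._two_electrode_arena()
        with pytest.raises(ValueError):
            vt.ventilatory_frequency_at(_track(np.zeros((4, 2))), self._maps(3),
                                        arena=arena)


class TestWindowing:
    def _velocity(self, speeds):
        n = len(speeds)
        xy = np.zeros((n, 2))
        vel = vt.VelocityTrack(t=np.arange(n) / 33.0,
                               v=np.column_stack([speeds, np.zeros(n)]),
                               degenerate=np.zeros(n, dtype=bool))
        return vel

    def test_300s_gives_60_windows(self):
        n = 9900  # 300 s at 33 Hz
        vel = self._velocity(np.full(n, 10.0))
        win = vt.windowed_indices(vel, np.full(n, 3.0))
        assert len(win) == 60

    def test_constant_series_zero_sds(self):
        n = 165 * 2
        win = vt.windowed_indices(self._velocity(np.full(n, 10.0)), np.full(n, 3.0))
        assert np.allclose(win["v_sd"], 0.0) and np.allclose(win["fv_sd"], 0.0)

    def test_alternating_speeds_by_hand(self):
        n = 165
        speeds = np.where(np.arange(n) % 2 == 0, 0.0, 20.0)
        win = vt.windowed_indices(self._velocity(speeds), np.full(n, 3.0), v_stop=5.0)
        assert win.loc[0, "p_stop"] == pytest.approx(100.0 * 83 / 165)
        assert win.loc[0, "v_mean"] == pytest.approx(speeds.mean())

    def test_trailing_partial_window_dropped(self):
        n = 165 + 80
        win = vt.windowed_indices(self._velocity(np.full(n, 1.0)), np.full(n, 3.0))
        assert len(win) == 1


class TestStandardise:
    def _table(self):
        rng = np.random.default_rng(5)
        rows = []
        for state, shift in (("normal", 0.0), ("fear", 2.0)):
            for w in range(20):
                rows.append({"fish_id": "f1", "state": state, "t0": float(w),
                             **{c: rng.normal(10.0 + shift, 2.0) for c in INDEX_COLUMNS},
                             "standardised": False})
        return pd.DataFrame(rows)

    def test_baseline_scored_to_zero_mean_unit_sd(self):
        out = vt.standardise(self._table())
        base = out[out["state"] == "normal"]
        assert np.allclose(base[INDEX_COLUMNS].mean(), 0.0, atol=1e-12)
        assert np.allclose(base[INDEX_COLUMNS].std(ddof=1), 1.0, atol=1e-12)

    def test_hand_value(self):
        table = self._table()
        base = table[table["state"] == "normal"]
        mu = base["v_mean"].mean()
        sd = base["v_mean"].std(ddof=1)
        out = vt.standardise(table)
        expect = (table.loc[25, "v_mean"] - mu) / sd
        assert out.loc[25, "v_mean"] == pytest.approx(expect)

    def test_idempotent(self):
        once = vt.standardise(self._table())
        twice = vt.standardise(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_zero_baseline_sd_names_the_index(self):
        table = self._table()
        table.loc[table["state"] == "normal", "fv_sd"] = 1.0
        with pytest.raises(ValueError, match="fv_sd"):
            vt.standardise(table)
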