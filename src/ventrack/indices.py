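"""The six evaluation indices and their per-window standardisation.

Per 5 s window of the 33 Hz track the indices are: (i) mean swimming speed,
(ii) stopping probability P_stop = 100 * (time below v_stop) / T_index,
(iii) mean ventilatory frequency F_v, and (iv-vi) the within-window SDs of
speed, stopping probability (over 1 s sub-windows) and F_v.  Windows are
then standardised per fish against that fish's baseline (normal-state)
windows: baseline mean -> 0, baseline SD -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .position import F_M, PositionTrack
from .signal_processing import PeakMap

__all__ = [
    "INDEX_COLUMNS",
    "VelocityTrack",
    "differentiate_positions",
    "stopping_probability",
    "ventilatory_frequency_at",
    "windowed_indices",
    "standardise",
]

#: the six index columns, in radar-chart order
INDEX_COLUMNS = ["v_mean", "p_stop", "fv_mean", "v_sd", "p_stop_sd", "fv_sd"]


@dataclass(eq=False)
class VelocityTrack:
    """Estimated swimming velocity on the analysis-tick grid."""

    t: np.ndarray        # (n,) s
    v: np.ndarray        # (n, 2) mm/s
    degenerate: np.ndarray

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v[:, 0], self.v[:, 1])

    def __len__(self) -> int:
        return int(self.t.shape[0])


def differentiate_positions(track: PositionTrack, f_cut2: float = 2.0,
                            order: int = 4, f_m: float = F_M) -> VelocityTrack:
    """Central-difference velocity followed by a zero-phase low-pass."""
    if len(track) < 3:
        raise ValueError("need at least 3 ticks to differentiate a track")
    v = np.gradient(track.xy, track.t, axis=0)
    sos = butter(order, f_cut2, btype="lowpass", fs=f_m, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), len(track) - 1)
    v = sosfiltfilt(sos, v, axis=0, padlen=padlen)
    return VelocityTrack(t=track.t, v=v, degenerate=track.degenerate)


def stopping_probability(speeds: np.ndarray, v_stop: float) -> float:
    """Percentage of the window during which speed stays below ``v_stop``."""
    speeds = np.asarray(speeds, dtype=float)
    if speeds.size == 0:
        raise ValueError("empty window")
    return float(100.0 * np.count_nonzero(speeds < v_stop) / speeds.size)


def ventilatory_frequency_at(track: PositionTrack, maps: list[PeakMap],
                             arena=None) -> np.ndarray:
    """Per-tick ventilatory frequency: the peak frequency at the estimated position.

    Reads the peak frequency of the electrode nearest the estimated position
    at each tick.  Degenerate ticks carry the previous value forward.
    """
    if len(track) != len(maps):
        raise ValueError("track and peak maps must share the tick grid")
    if arena is None:
        raise ValueError("arena geometry is required for the nearest-electrode lookup")
    nearest = arena.nearest_electrode(track.xy)
    fv = np.array([maps[i].peak_freq[nearest[i]] for i in range(len(maps))])
    for i in range(1, len(fv)):
        if track.degenerate[i]:
            fv[i] = fv[i - 1]
    return fv


def windowed_indices(
    velocity: VelocityTrack,
    fv: np.ndarray,
    window: float = 5.0,
    v_stop: float = 3.0,
    sub_window: float = 1.0,
    f_m: float = F_M,
    fish_id: str = "fish",
    state: str = "normal",
) -> pd.DataFrame:
    """Aggregate tick series into per-window index rows.

    The tick series is cut into consecutive ``window``-second windows (any
    trailing partial window is dropped).  The SD of the stopping probability
    is taken over ``sub_window``-second sub-windows within each window.
    """
    fv = np.asarray(fv, dtype=float)
    if len(fv) != len(velocity):
        raise ValueError("velocity track and F_v series must share the tick grid")
    n_per_win = int(round(window * f_m))
    if n_per_win < 3:
        raise ValueError("window must span at least 3 ticks")
    n_sub = int(round(sub_window * f_m))
    subs_per_win = n_per_win // n_sub
    speeds = velocity.speed
    n_win = len(speeds) // n_per_win
    rows = []
    for w in range(n_win):
        lo = w * n_per_win
        s = speeds[lo:lo + n_per_win]
        f = fv[lo:lo + n_per_win]
        p_sub = [
            stopping_probability(s[j * n_sub:(j + 1) * n_sub], v_stop)
            for j in range(subs_per_win)
        ]
        rows.append(
            {
                "fish_id": fish_id,
                "state": state,
                "t0": float(velocity.t[lo]),
                "v_mean": float(s.mean()),
                "p_stop": stopping_probability(s, v_stop),
                "fv_mean": float(f.mean()),
                "v_sd": float(s.std(ddof=1)),
                "p_stop_sd": float(np.std(p_sub, ddof=1)),
                "fv_sd": float(f.std(ddof=1)),
                "standardised": False,
            }
        )
    return pd.DataFrame(rows)


def standardise(table: pd.DataFrame, baseline_state: str = "normal") -> pd.DataFrame:
    """Per-fish z-scoring of the six indices against baseline windows.

    For every fish, the mean and SD of each index over that fish's
    ``baseline_state`` windows define the transform applied to all of the
    fish's windows.  A fish without baseline windows falls back to its first
    state.  Already-standardised tables pass through idempotently (the
    baseline is re-scored to mean 0 / SD 1, which it already has).
    """
    table = table.copy()
    for fish, grp in table.groupby("fish_id", sort=False):
        base = grp[grp["state"] == baseline_state]
        if len(base) == 0:
            base = grp[grp["state"] == grp["state"].iloc[0]]
        if len(base) < 2:
            raise ValueError(f"fish {fish!r}: baseline needs at least 2 windows")
        mu = base[INDEX_COLUMNS].mean()
        sd = base[INDEX_COLUMNS].std(ddof=1)
        zero = sd[sd == 0.0]
        if len(zero) > 0:
            raise ValueError(
                f"fish {fish!r}: zero baseline SD for index {zero.index[0]!r}"
            )
        table.loc[grp.index, INDEX_COLUMNS] = (
            (grp[INDEX_COLUMNS] - mu) / sd
        ).to_numpy()
    table["standardised"] = True
    return table
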