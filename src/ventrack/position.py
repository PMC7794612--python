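"""Fish position from the spatial distribution of spectral peak power.

Per tick, the per-electrode peak powers are spline-interpolated (bicubic, the
electrode spacing divided into five equal parts), the power-weighted centre
of gravity of the refined surface is taken as the raw position, and the raw
track is finished with a zero-phase low-pass filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline
from scipy.signal import butter, sosfiltfilt

from .arena import ArenaGeometry
from .signal_processing import F_M, PeakMap

__all__ = [
    "F_M",
    "UnsupportedLayoutError",
    "PositionTrack",
    "interpolate_peak_surface",
    "centre_of_gravity",
    "smooth_track",
    "estimate_track",
]


class UnsupportedLayoutError(ValueError):
    """Electrode layout is not the regular grid the spline stage assumes."""


@dataclass(eq=False)
class PositionTrack:
    """Estimated fish track on the analysis-tick grid."""

    t: np.ndarray            # (n,) s
    xy: np.ndarray           # (n, 2) mm, smoothed estimate
    xy_raw: np.ndarray       # (n, 2) mm, pre-smoothing centre of gravity
    degenerate: np.ndarray   # (n,) bool, True where power vanished and the
                             # estimate was held from the previous tick

    def __len__(self) -> int:
        return int(self.t.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x_raw": self.xy_raw[:, 0], "y_raw": self.xy_raw[:, 1],
                "x": self.xy[:, 0], "y": self.xy[:, 1],
                "degenerate_flag": self.degenerate.astype(int),
            }
        )


def interpolate_peak_surface(
    pmap: PeakMap,
    arena: ArenaGeometry,
    subdivisions: int = 5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bicubic-spline refinement of the peak-power field on the electrode grid.

    Returns ``(xs, ys, power)`` where ``power`` has shape ``(len(xs), len(ys))``
    and the refined axes place ``subdivisions`` equal parts between adjacent
    electrodes.  Negative interpolants are clamped to zero.
    """
    if arena.grid_shape is None:
        raise UnsupportedLayoutError("peak-surface interpolation needs a regular grid")
    nx, ny = arena.grid_shape
    gx, gy = arena.grid_axes()
    power = np.asarray(pmap.peak_power, dtype=float).reshape(nx, ny)
    xs = np.linspace(gx[0], gx[-1], (nx - 1) * subdivisions + 1)
    ys = np.linspace(gy[0], gy[-1], (ny - 1) * subdivisions + 1)
    spline = RectBivariateSpline(gx, gy, power, kx=3, ky=3, s=0)
    dense = spline(xs, ys)
    return xs, ys, np.clip(dense, 0.0, None)


def centre_of_gravity(xs: np.ndarray, ys: np.ndarray,
                      power: np.ndarray) -> tuple[float, float]:
    """Power-weighted mean coordinate of a dense power grid."""
    total = power.sum()
    if total <= 0.0:
        raise ValueError("centre of gravity needs at least one positive power value")
    px = (power.sum(axis=1) * xs).sum() / total
    py = (power.sum(axis=0) * ys).sum() / total
    return float(px), float(py)


def smooth_track(
    t: np.ndarray,
    xy_raw: np.ndarray,
    f_cut1: float = 2.0,
    order: int = 4,
    f_m: float = F_M,
    arena: ArenaGeometry | None = None,
    degenerate: np.ndarray | None = None,
) -> PositionTrack:
    """Zero-phase low-pass the raw centre-of-gravity track per coordinate."""
    t = np.asarray(t, dtype=float)
    xy_raw = np.asarray(xy_raw, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 ticks to smooth a track")
    if f_cut1 >= f_m / 2.0:
        raise ValueError("f_cut1 must lie below the analysis Nyquist rate f_m/2")
    sos = butter(order, f_cut1, btype="lowpass", fs=f_m, output="sos")
    padlen = min(3 * (2 * sos.shape[0] + 1), len(t) - 1)
    xy = sosfiltfilt(sos, xy_raw, axis=0, padlen=padlen)
    if arena is not None:
        xy[:, 0] = np.clip(xy[:, 0], 0.0, arena.width_x)
        xy[:, 1] = np.clip(xy[:, 1], 0.0, arena.width_y)
    if degenerate is None:
        degenerate = np.zeros(len(t), dtype=bool)
    return PositionTrack(t=t, xy=xy, xy_raw=xy_raw, degenerate=degenerate)


def estimate_track(
    maps: list[PeakMap],
    arena: ArenaGeometry,
    subdivisions: int = 5,
    f_cut1: float = 2.0,
    order: int = 4,
    f_m: float = F_M,
) -> PositionTrack:
    """Full localisation chain: spline surface -> centre of gravity -> smoothing.

    Ticks whose power field is identically zero (signal lost) hold the
    previous estimate — or the arena centre if there is none yet — and are
    flagged degenerate.
    """
    if len(maps) < 3:
        raise ValueError("need at least 3 peak maps")
    raw = np.empty((len(maps), 2))
    degen = np.zeros(len(maps), dtype=bool)
    prev: tuple[float, float] | None = None
    for i, pmap in enumerate(maps):
        try:
            xs, ys, dense = interpolate_peak_surface(pmap, arena, subdivisions)
            prev = centre_of_gravity(xs, ys, dense)
        except ValueError as err:
            if isinstance(err, UnsupportedLayoutError):
                raise
            degen[i] = True
            if prev is None:
                prev = arena.centre
                warnings.warn("all-zero power map before any valid tick; "
                              "falling back to the arena centre", stacklevel=2)
        raw[i] = prev
    t = np.array([m.t for m in maps])
    return smooth_track(t, raw, f_cut1=f_cut1, order=order, f_m=f_m,
                        arena=arena, degenerate=degen)
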