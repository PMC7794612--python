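"""HDF5 / CSV serialisation of recordings, peak maps and tracks.

Recording schema (HDF5): ``/signals`` (channels x time), ``/electrode_xy``
(L x 2, mm), ``/fs`` (scalar Hz), arena attributes on the root group, and an
optional ``/truth`` group (``t, x, y, vx, vy, fv, state``).  Peak-map
sequences use ``/peaks/t``, ``/peaks/freq``, ``/peaks/power`` plus the AR
order and band as attributes.
"""

from __future__ import annotations

import numpy as np

from .arena import ArenaGeometry
from .signal_processing import PeakMap
from .simulate import ElectrodeArrayRecording, GroundTruthTrajectory

__all__ = [
    "save_recording",
    "load_recording",
    "save_peak_maps",
    "load_peak_maps",
]


def save_recording(path, rec: ElectrodeArrayRecording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.samples, compression="gzip")
        f.create_dataset("electrode_xy", data=rec.arena.electrode_positions)
        f.create_dataset("fs", data=float(rec.fs))
        f.attrs["width_x"] = rec.arena.width_x
        f.attrs["width_y"] = rec.arena.width_y
        f.attrs["pitch"] = rec.arena.pitch
        if rec.arena.grid_shape is not None:
            f.attrs["grid_shape"] = rec.arena.grid_shape
        if rec.band is not None:
            f.attrs["band"] = rec.band
        if rec.truth is not None:
            g = f.create_group("truth")
            tr = rec.truth
            g.create_dataset("t", data=tr.t)
            g.create_dataset("x", data=tr.xy[:, 0])
            g.create_dataset("y", data=tr.xy[:, 1])
            g.create_dataset("vx", data=tr.v[:, 0])
            g.create_dataset("vy", data=tr.v[:, 1])
            g.create_dataset("fv", data=tr.fv)
            g.create_dataset("state", data=np.asarray(tr.state, dtype="S"))
            g.attrs["fish_id"] = tr.fish_id


def load_recording(path) -> ElectrodeArrayRecording:
    import h5py

    with h5py.File(path, "r") as f:
        arena = ArenaGeometry(
            width_x=float(f.attrs["width_x"]),
            width_y=float(f.attrs["width_y"]),
            electrode_positions=f["electrode_xy"][()],
            pitch=float(f.attrs["pitch"]),
            grid_shape=tuple(int(v) for v in f.attrs["grid_shape"])
            if "grid_shape" in f.attrs else None,
        )
        truth = None
        if "truth" in f:
            g = f["truth"]
            xy = np.column_stack([g["x"][()], g["y"][()]])
            v = np.column_stack([g["vx"][()], g["vy"][()]])
            truth = GroundTruthTrajectory(
                t=g["t"][()], xy=xy, v=v, fv=g["fv"][()],
                state=g["state"][()].astype(str),
                fish_id=str(g.attrs.get("fish_id", "fish")), arena=arena,
            )
        band = tuple(float(v) for v in f.attrs["band"]) if "band" in f.attrs else None
        return ElectrodeArrayRecording(
            samples=f["signals"][()], fs=float(f["fs"][()]), arena=arena,
            truth=truth, band=band,
        )


def save_peak_maps(path, maps: list[PeakMap]) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("peaks")
        g.create_dataset("t", data=np.array([m.t for m in maps]))
        g.create_dataset("freq", data=np.stack([m.peak_freq for m in maps]))
        g.create_dataset("power", data=np.stack([m.peak_power for m in maps]))
        g.attrs["ar_order"] = maps[0].ar_order
        g.attrs["band"] = maps[0].band


def load_peak_maps(path) -> list[PeakMap]:
    import h5py

    with h5py.File(path, "r") as f:
        g = f["peaks"]
        t = g["t"][()]
        freq = g["freq"][()]
        power = g["power"][()]
        order = int(g.attrs["ar_order"])
        band = tuple(float(v) for v in g.attrs["band"])
    return [
        PeakMap(t=float(t[i]), peak_freq=freq[i], peak_power=power[i],
                ar_order=order, band=band)
        for i in range(len(t))
    ]
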