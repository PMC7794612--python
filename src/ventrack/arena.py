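"""Measurement arena and electrode-array geometry.

The reference setup is a shallow 210 x 140 mm aquarium with a 126-electrode
Ag-AgCl array fixed to the bottom, arranged as a regular 14 x 9 grid
(15 mm pitch).  Electrode positions are stored x-major: the electrode at
grid cell (ix, iy) sits at flat index ``ix * ny + iy``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ArenaGeometry", "default_arena"]


@dataclass(eq=False)
class ArenaGeometry:
    """Arena bounding box plus electrode layout.

    Parameters
    ----------
    width_x, width_y:
        Inner arena dimensions in mm.
    electrode_positions:
        ``(L, 2)`` array of electrode (x, y) coordinates in mm.
    pitch:
        Electrode spacing in mm (regular grids only; kept for kernels and
        error scales even for irregular layouts).
    grid_shape:
        ``(nx, ny)`` if the electrodes form a regular grid in x-major
        order, else ``None``.
    """

    width_x: float = 210.0
    width_y: float = 140.0
    electrode_positions: np.ndarray = field(default=None)  # type: ignore[assignment]
    pitch: float = 15.0
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.electrode_positions is None:
            raise ValueError("electrode_positions is required (see default_arena())")
        pos = np.asarray(self.electrode_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise ValueError("electrode_positions must be a non-empty (L, 2) array")
        if (
            pos[:, 0].min() < 0
            or pos[:, 0].max() > self.width_x
            or pos[:, 1].min() < 0
            or pos[:, 1].max() > self.width_y
        ):
            raise ValueError("all electrode positions must lie inside the arena")
        if self.grid_shape is not None:
            nx, ny = self.grid_shape
            if nx * ny != pos.shape[0]:
                raise ValueError("grid_shape inconsistent with electrode count")
        self.electrode_positions = pos

    @property
    def n_electrodes(self) -> int:
        return int(self.electrode_positions.shape[0])

    @property
    def centre(self) -> tuple[float, float]:
        return (self.width_x / 2.0, self.width_y / 2.0)

    def grid_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique, sorted x and y node coordinates of a regular grid."""
        if self.grid_shape is None:
            raise ValueError("arena does not declare a regular electrode grid")
        nx, ny = self.grid_shape
        xs = self.electrode_positions[::ny, 0]
        ys = self.electrode_positions[:ny, 1]
        return xs, ys

    def nearest_electrode(self, xy: np.ndarray) -> np.ndarray:
        """Index of the electrode closest to each query point (``(..., 2)``)."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        d2 = ((xy[:, None, :] - self.electrode_positions[None, :, :]) ** 2).sum(-1)
        return np.argmin(d2, axis=1)


def default_arena() -> ArenaGeometry:
    """The 126-electrode reference arena: 14 x 9 grid, 15 mm pitch, centred."""
    nx, ny, pitch = 14, 9, 15.0
    x0 = (210.0 - (nx - 1) * pitch) / 2.0
    y0 = (140.0 - (ny - 1) * pitch) / 2.0
    xs = x0 + pitch * np.arange(nx)
    ys = y0 + pitch * np.arange(ny)
    pos = np.array([(x, y) for x in xs for y in ys])
    return ArenaGeometry(
        width_x=210.0,
        width_y=140.0,
        electrode_positions=pos,
        pitch=pitch,
        grid_shape=(nx, ny),
    )
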