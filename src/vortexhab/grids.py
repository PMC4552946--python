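"""Cell-centered cross-section grids.

A transect through the channel is discretised on a structured, cell-centered
y-z grid: ``y`` is the transverse coordinate (left bank at 0, facing
downstream), ``z`` is vertical and positive upward from the channel invert.
Each cell carries the in-plane velocity components ``v_y`` and ``v_z`` and a
wet/dry flag; the bed elevation ``z_bed(y)`` is stored per column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CrossSectionGrid"]


@dataclass
class CrossSectionGrid:
    """Structured cell-centered grid of in-plane velocities on a transect.

    Arrays are indexed ``[i, j]`` with ``i`` the vertical (z) index increasing
    upward and ``j`` the transverse (y) index increasing left to right.

    Parameters
    ----------
    y : (ny,) cell-center transverse coordinates, m
    z : (nz,) cell-center vertical coordinates, m (above channel invert)
    dy, dz : uniform cell sizes, m
    v_y, v_z : (nz, ny) in-plane velocity components, m/s
    wet : (nz, ny) boolean mask; True where the cell center is submerged
    z_bed : (ny,) bed elevation per column, m
    water_surface : free-surface elevation above the invert, m
    """

    y: np.ndarray
    z: np.ndarray
    dy: float
    dz: float
    v_y: np.ndarray
    v_z: np.ndarray
    wet: np.ndarray
    z_bed: np.ndarray
    water_surface: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        self.v_y = np.asarray(self.v_y, dtype=float)
        self.v_z = np.asarray(self.v_z, dtype=float)
        self.wet = np.asarray(self.wet, dtype=bool)
        self.z_bed = np.asarray(self.z_bed, dtype=float)
        if self.dy <= 0 or self.dz <= 0:
            raise ValueError("cell sizes dy, dz must be positive")
        nz, ny = self.v_y.shape
        if self.y.shape != (ny,) or self.z.shape != (nz,):
            raise ValueError("coordinate vectors inconsistent with field shape")
        if self.v_z.shape != (nz, ny) or self.wet.shape != (nz, ny):
            raise ValueError("field arrays must share one (nz, ny) shape")
        if self.z_bed.shape != (ny,):
            raise ValueError("z_bed must have one entry per column")
        if not np.all(np.isfinite(self.v_y[self.wet])) or not np.all(
            np.isfinite(self.v_z[self.wet])
        ):
            raise ValueError("velocities must be finite on wet cells")

    @property
    def ny(self) -> int:
        return self.y.size

    @property
    def nz(self) -> int:
        return self.z.size

    @property
    def cell_area(self) -> float:
        """Area of one cell, m^2 (uniform grid)."""
        return self.dy * self.dz

    @property
    def n_wet(self) -> int:
        return int(self.wet.sum())

    @property
    def wetted_area(self) -> float:
        """Discrete wetted cross-sectional area, m^2 (wet-cell count x cell area)."""
        return self.n_wet * self.cell_area

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (yy, zz) cell-center coordinate arrays of shape (nz, ny)."""
        return np.meshgrid(self.y, self.z)

    def copy(self) -> "CrossSectionGrid":
        return replace(
            self,
            y=self.y.copy(),
            z=self.z.copy(),
            v_y=self.v_y.copy(),
            v_z=self.v_z.copy(),
            wet=self.wet.copy(),
            z_bed=self.z_bed.copy(),
        )
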