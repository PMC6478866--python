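"""Flat equal-area analysis grid and named environmental layer stacks.

All spatial analysis runs on a Cartesian grid of square cells with
coordinates in kilometres.  A global 5-km analysis grid is treated as
equal-area; no geodesy is performed.  Rasters are plain 2-D numpy arrays
indexed ``[row, col]`` with row 0 at the grid origin (y increases with
row index, x with column index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

VARIABLE_SETS = ("edaphic", "geophysical", "climatic")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; must be at least 1.
    cell_size_km : float
        Edge length of the square cells, km.  Default 5 km, matching a
        global 5 km x 5 km analysis resolution.
    origin : tuple of float
        (x0, y0) of the grid's lower-left corner, km.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) centre coordinates as 2-D arrays of grid shape."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size_km
        ys = y0 + (np.arange(self.n_rows) + 0.5) * self.cell_size_km
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates (km) to integer (row, col); out-of-grid -> -1."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin[0]) / self.cell_size_km).astype(int)
        row = np.floor((y - self.origin[1]) / self.cell_size_km).astype(int)
        bad = (row < 0) | (row >= self.n_rows) | (col < 0) | (col >= self.n_cols)
        row = np.where(bad, -1, row)
        col = np.where(bad, -1, col)
        return row, col

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, _ = self.xy_to_rowcol(x, y)
        return row >= 0


@dataclass
class EnvStack:
    """A stack of environmental layers on a shared grid.

    Each layer is tagged with one of the three variable sets used for
    ecogeographic land characterization: edaphic, geophysical or climatic.
    ``epoch`` is "baseline" or the name of a future climate realization.
    """

    grid: GridSpec
    layers: dict[str, np.ndarray]
    sets: dict[str, str]
    epoch: str = "baseline"

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            if arr.shape != self.grid.shape:
                raise ValueError(f"layer {name!r} shape {arr.shape} != grid {self.grid.shape}")
            if name not in self.sets:
                raise ValueError(f"layer {name!r} has no variable-set tag")
            if self.sets[name] not in VARIABLE_SETS:
                raise ValueError(f"unknown variable set {self.sets[name]!r} for {name!r}")

    @property
    def variables(self) -> list[str]:
        return list(self.layers)

    def variables_in_set(self, set_name: str) -> list[str]:
        if set_name not in VARIABLE_SETS:
            raise ValueError(f"unknown variable set {set_name!r}")
        return [v for v in self.layers if self.sets[v] == set_name]

    def values(self, variables: Iterable[str] | None = None, mask: np.ndarray | None = None) -> np.ndarray:
        """Cell values as an (n_cells, n_vars) matrix, optionally masked.

        Cell order is row-major over the grid (or over ``mask`` true cells).
        """
        names = list(variables) if variables is not None else self.variables
        cols = []
        for v in names:
            arr = self.layers[v]
            cols.append(arr[mask] if mask is not None else arr.ravel())
        return np.column_stack(cols) if cols else np.empty((0, 0))

    def copy(self) -> "EnvStack":
        return EnvStack(
            grid=self.grid,
            layers={k: v.copy() for k, v in self.layers.items()},
            sets=dict(self.sets),
            epoch=self.epoch,
        )


def mean_stack(stacks: list[EnvStack], epoch: str = "mean") -> EnvStack:
    """Cellwise mean of several stacks sharing grid and variables."""
    if not stacks:
        raise ValueError("need at least one stack")
    first = stacks[0]
    for s in stacks[1:]:
        if s.grid != first.grid or set(s.layers) != set(first.layers):
            raise ValueError("stacks do not share grid/variables")
    layers = {
        v: np.mean([s.layers[v] for s in stacks], axis=0) for v in first.layers
    }
    return EnvStack(grid=first.grid, layers=layers, sets=dict(first.sets), epoch=epoch)
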