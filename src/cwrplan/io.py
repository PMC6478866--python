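"""Plain-text raster and table I/O.

Rasters are stored as ESRI ASCII grids (``.asc``), a simple header plus
whitespace-separated values; layer-set tags and grid provenance travel in
sidecar CSV/JSON files.  Occurrence and report tables are CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import EnvStack, GridSpec


def write_ascii_grid(path: str | Path, array: np.ndarray, grid: GridSpec) -> None:
    """Write a 2-D array as an ESRI ASCII grid.

    Row 0 of the array is the southernmost row; the file is written
    north-up as the format expects.
    """
    path = Path(path)
    arr = np.asarray(array)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]}\n"
        f"yllcorner {grid.origin[1]}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value -9999\n"
    )
    body = arr[::-1]  # north-up
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        body = np.loadtxt(fh)
    grid = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        cell_size_km=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    arr = np.atleast_2d(body)[::-1]
    return arr, grid


def write_env_stack(directory: str | Path, stack: EnvStack) -> None:
    """One ``.asc`` per layer plus a ``layers.csv`` tag table."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, arr in stack.layers.items():
        write_ascii_grid(directory / f"{name}.asc", arr, stack.grid)
        rows.append({"variable": name, "set": stack.sets[name], "epoch": stack.epoch})
    pd.DataFrame(rows).to_csv(directory / "layers.csv", index=False)


def read_env_stack(directory: str | Path) -> EnvStack:
    directory = Path(directory)
    tags = pd.read_csv(directory / "layers.csv")
    layers: dict[str, np.ndarray] = {}
    sets: dict[str, str] = {}
    grid = None
    for _, row in tags.iterrows():
        arr, grid = read_ascii_grid(directory / f"{row['variable']}.asc")
        layers[row["variable"]] = arr
        sets[row["variable"]] = row["set"]
    epoch = str(tags["epoch"].iloc[0]) if len(tags) else "baseline"
    return EnvStack(grid=grid, layers=layers, sets=sets, epoch=epoch)


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
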