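"""Climate raster stacks on a regular lon/lat grid.

A :class:`ClimateStack` holds one named layer per climate variable on a
shared grid with a boolean range mask.  Stacks are stored on disk as
plain whitespace-delimited grids (one file per layer) plus a small JSON
header with the grid geometry, so a stack round-trips losslessly through
text files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ClimateStack"]


@dataclass
class ClimateStack:
    """Named co-registered raster layers for one climate scenario.

    Parameters
    ----------
    names
        Layer (variable) names, e.g. ``["bio1", "bio12"]``.
    data
        Array of shape ``(n_layers, rows, cols)``; cells outside the
        mask are NaN.
    lon, lat
        Cell-centre coordinates: ``lon`` has length ``cols`` (ascending),
        ``lat`` has length ``rows`` (descending, row 0 is northernmost).
    mask
        Boolean ``(rows, cols)`` range mask; True = inside the range.
    """

    names: list[str]
    data: np.ndarray
    lon: np.ndarray
    lat: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_layers, rows, cols)")
        if self.data.shape[0] != len(self.names):
            raise ValueError("one name per layer required")
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        rows, cols = self.data.shape[1:]
        if self.lon.shape != (cols,) or self.lat.shape != (rows,):
            raise ValueError("lon/lat lengths must match grid shape")
        if self.mask is None:
            self.mask = np.ones((rows, cols), dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (rows, cols):
            raise ValueError("mask shape must match grid shape")

    # -- basic accessors -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def layer(self, name: str) -> np.ndarray:
        try:
            i = self.names.index(name)
        except ValueError:
            raise KeyError(f"no such layer: {name!r}") from None
        return self.data[i]

    def cell_lonlat(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell lon/lat grids of shape (rows, cols)."""
        glon, glat = np.meshgrid(self.lon, self.lat)
        return glon, glat

    def masked_table(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flatten in-mask cells to (values, lon, lat).

        ``values`` has shape ``(n_cells, n_layers)`` in layer order; cell
        order is row-major over the grid (stable across calls).
        """
        glon, glat = self.cell_lonlat()
        m = self.mask.ravel()
        vals = self.data.reshape(len(self.names), -1).T[m]
        return vals, glon.ravel()[m], glat.ravel()[m]

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        r = int(np.argmin(np.abs(self.lat - lat)))
        c = int(np.argmin(np.abs(self.lon - lon)))
        return r, c

    def values_at(self, lon, lat) -> np.ndarray:
        """Sample all layers at point locations by nearest cell centre.

        Returns shape ``(n_points, n_layers)``.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        out = np.empty((len(lon), len(self.names)))
        for i, (x, y) in enumerate(zip(lon, lat)):
            r, c = self.nearest_cell(x, y)
            out[i] = self.data[:, r, c]
        return out

    # -- arithmetic ------------------------------------------------------

    def copy(self) -> "ClimateStack":
        return ClimateStack(list(self.names), self.data.copy(),
                            self.lon.copy(), self.lat.copy(), self.mask.copy())

    def select(self, names: list[str]) -> "ClimateStack":
        idx = [self.names.index(n) for n in names]
        return ClimateStack(list(names), self.data[idx].copy(),
                            self.lon.copy(), self.lat.copy(), self.mask.copy())

    # -- text I/O --------------------------------------------------------

    def to_dir(self, path: str | Path) -> None:
        """Write the stack as text grids (one ``<name>.grd`` per layer)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        header = {
            "names": self.names,
            "lon": self.lon.tolist(),
            "lat": self.lat.tolist(),
        }
        (path / "stack.json").write_text(json.dumps(header, indent=1))
        np.savetxt(path / "mask.grd", self.mask.astype(int), fmt="%d")
        for i, name in enumerate(self.names):
            np.savetxt(path / f"{name}.grd", self.data[i], fmt="%.10g")

    @classmethod
    def from_dir(cls, path: str | Path) -> "ClimateStack":
        path = Path(path)
        header = json.loads((path / "stack.json").read_text())
        mask = np.loadtxt(path / "mask.grd").astype(bool)
        mask = np.atleast_2d(mask)
        data = np.stack([np.atleast_2d(np.loadtxt(path / f"{n}.grd"))
                         for n in header["names"]])
        return cls(header["names"], data,
                   np.asarray(header["lon"]), np.asarray(header["lat"]), mask)
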