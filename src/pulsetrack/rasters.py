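"""Lightweight raster stack on a regular grid of projected meters.

All layers share one grid: square cells of ``cell_size`` meters, origin at
the lower-left corner ``(x0, y0)``, arrays stored row-major from the top-left
(row 0 = northernmost row).  Sampling is nearest-cell, matching 30-m pixel
semantics; no interpolation, no geodesy.

Persistence uses ESRI ASCII grids (one ``.asc`` per layer) plus a JSON
sidecar (``layers.json``) naming the layers and flagging categorical ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterStack", "distance_layer"]

_NODATA = -9999.0


@dataclass
class RasterStack:
    """A named set of co-registered single-band rasters.

    Parameters
    ----------
    layers
        Mapping layer name -> 2-D float array, all the same shape.
    cell_size
        Cell edge in meters.
    origin
        ``(x0, y0)`` of the lower-left corner of the lower-left cell.
    categorical
        Names of layers holding integer class codes (sampled without
        standardization downstream).
    class_labels
        Optional mapping layer name -> {code: label} for categorical layers.
    """

    layers: dict[str, np.ndarray]
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    categorical: set[str] = field(default_factory=set)
    class_labels: dict[str, dict[int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.layers.values()}
        if len(shapes) > 1:
            raise ValueError(f"layers disagree on shape: {shapes}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def nrows(self) -> int:
        return self.shape[0]

    @property
    def ncols(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid's outer edge."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    def names(self) -> list[str]:
        return list(self.layers)

    # -- coordinate <-> index -------------------------------------------------

    def rowcol(self, x, y):
        """Nearest-cell (row, col) for point arrays; may be out of bounds."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = self.nrows - 1 - np.floor((y - y0) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col):
        """(x, y) of cell centers for index arrays."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def in_bounds(self, x, y):
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def sample(self, x, y, layer: str):
        """Nearest-cell values of one layer at points; NaN out of bounds."""
        arr = self.layers[layer]
        row, col = self.rowcol(x, y)
        ok = self.in_bounds(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        if np.any(ok):
            r = np.where(ok, row, 0)
            c = np.where(ok, col, 0)
            vals = arr[r, c].astype(float)
            out = np.where(ok, vals, np.nan)
        return out if out.shape else float(out)

    # -- persistence ----------------------------------------------------------

    def write(self, directory: str | Path) -> None:
        """One ESRI ASCII grid per layer plus a ``layers.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        x0, y0 = self.origin
        header = (
            f"ncols {self.ncols}\nnrows {self.nrows}\n"
            f"xllcorner {x0!r}\nyllcorner {y0!r}\n"
            f"cellsize {self.cell_size!r}\nNODATA_value {_NODATA}\n"
        )
        for name, arr in self.layers.items():
            a = np.where(np.isfinite(arr), arr, _NODATA)
            with open(directory / f"{name}.asc", "w") as fh:
                fh.write(header)
                np.savetxt(fh, a, fmt="%.10g")
        sidecar = {
            "layers": self.names(),
            "categorical": sorted(self.categorical),
            "class_labels": {
                k: {str(c): lab for c, lab in v.items()} for k, v in self.class_labels.items()
            },
        }
        (directory / "layers.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "RasterStack":
        directory = Path(directory)
        sidecar = json.loads((directory / "layers.json").read_text())
        layers: dict[str, np.ndarray] = {}
        cell_size = None
        origin = (0.0, 0.0)
        for name in sidecar["layers"]:
            path = directory / f"{name}.asc"
            meta: dict[str, float] = {}
            with open(path) as fh:
                for _ in range(6):
                    key, val = fh.readline().split()
                    meta[key.lower()] = float(val)
                arr = np.loadtxt(fh)
            arr = np.atleast_2d(arr)
            arr[arr == meta.get("nodata_value", _NODATA)] = np.nan
            layers[name] = arr
            cell_size = meta["cellsize"]
            origin = (meta["xllcorner"], meta["yllcorner"])
        class_labels = {
            k: {int(c): lab for c, lab in v.items()}
            for k, v in sidecar.get("class_labels", {}).items()
        }
        return cls(
            layers=layers,
            cell_size=float(cell_size),
            origin=origin,
            categorical=set(sidecar.get("categorical", [])),
            class_labels=class_labels,
        )


def distance_layer(feature_mask: np.ndarray, cell_size: float) -> np.ndarray:
    """Euclidean distance (m) from every cell center to the nearest feature cell.

    ``feature_mask`` is a boolean array marking feature cells (roads, water).
    Distances are between cell centers, so a feature cell itself is at 0.
    """
    from scipy.ndimage import distance_transform_edt

    if not feature_mask.any():
        raise ValueError("feature mask is empty; cannot compute distances")
    return distance_transform_edt(~feature_mask.astype(bool)) * float(cell_size)
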