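"""Minimal categorical/continuous raster containers and TIFF round-trip I/O.

Rasters are plain numpy arrays wrapped with the two pieces of geometry the
pipeline needs: a square cell size in metres and an integer nodata code
(0 for categorical layers).  Files are written as single-band TIFFs via
:mod:`tifffile` with a JSON sidecar (``<name>.json``) holding the cell size,
nodata code and any provenance (seeds, injected transition matrices) so a
raster round-trips bit-exactly through disk.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

NODATA = 0

#: primary land-use codes, in the order used by every matrix in the package
LAND_USE_CODES = (1, 2, 3, 4, 5, 6)
LAND_USE_NAMES = {
    1: "cultivated",
    2: "woodland",
    3: "grassland",
    4: "water",
    5: "construction",
    6: "unused",
}

#: production-living-ecological space codes
PLE_CODES = (1, 2, 3, 4)
PLE_NAMES = {
    1: "living-production",
    2: "production-ecological",
    3: "ecological-production",
    4: "ecological",
}


@dataclass
class Raster:
    """A single-band raster: integer class codes or continuous values.

    Parameters
    ----------
    data
        2-D array.  Categorical rasters use positive integer codes with
        ``nodata`` marking masked cells; continuous rasters use floats.
    cell_size
        Side length of a (square) cell in metres.
    nodata
        Code marking masked cells in categorical data (ignored for floats).
    meta
        Free-form provenance written to the JSON sidecar.
    """

    data: np.ndarray
    cell_size: float = 30.0
    nodata: int = NODATA
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got shape {self.data.shape}")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def cell_area(self) -> float:
        """Area of one cell in m^2."""
        return self.cell_size**2

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        if np.issubdtype(self.data.dtype, np.floating):
            return ~np.isnan(self.data)
        return self.data != self.nodata

    def class_counts(self, codes=LAND_USE_CODES) -> np.ndarray:
        """Cell counts per class code, in the order of ``codes``."""
        return np.array([int(np.sum(self.data == c)) for c in codes])

    def class_areas_km2(self, codes=LAND_USE_CODES) -> np.ndarray:
        return self.class_counts(codes) * self.cell_area / 1e6

    def same_geometry(self, other: "Raster") -> bool:
        return self.shape == other.shape and self.cell_size == other.cell_size

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.cell_size, self.nodata, dict(self.meta))


def write_raster(raster: Raster, path: str | Path) -> Path:
    """Write a raster as a single-band TIFF plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, raster.data)
    sidecar = {
        "cell_size": raster.cell_size,
        "nodata": raster.nodata,
        "dtype": str(raster.data.dtype),
        "meta": _jsonable(raster.meta),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_raster(path: str | Path) -> Raster:
    """Read a raster written by :func:`write_raster`."""
    path = Path(path)
    data = tifffile.imread(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    cell_size, nodata, meta = 30.0, NODATA, {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        cell_size = sidecar.get("cell_size", cell_size)
        nodata = sidecar.get("nodata", nodata)
        meta = sidecar.get("meta", {})
    return Raster(data, cell_size=cell_size, nodata=nodata, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
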