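"""Grid-based spatial-conflict measurement on PLE rasters.

Each date's PLE raster is partitioned into square evaluation units
(1000 m by default).  Within every unit three landscape indices are
computed from the patch mosaic:

* **SCI** — spatial complexity, the area-weighted mean patch fractal
  dimension: ``sum_patches [2 ln(0.25 P) / ln(a)] * (a / A)`` with patch
  perimeter ``P`` and area ``a`` in metres and ``A`` the nominal unit area.
  Shape-complex, pressured mosaics score high; one square patch filling the
  unit scores exactly 1.
* **SVI** — spatial vulnerability, the area-weighted mean of per-space
  vulnerability scores (living-production 4, production-ecological 3,
  ecological-production 2, ecological 1).
* **SRI** — spatial stability, inverted min-max-scaled patch density
  (patch count / A); the most fragmented unit of a date scores 0, the most
  coherent 1.

The composite index ``SCCI = SCI + SVI - SRI`` is min-max normalized to
[0, 1] over a pool of units (all dates jointly by default, so conflict
levels are comparable across years) and cut into five equal-interval levels.

Boundary units that the raster only partly covers are kept and evaluated
against the full nominal unit area ``A`` in every denominator.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import PLE_CODES, PLE_NAMES, Raster

log = logging.getLogger(__name__)

#: vulnerability score per PLE space (LP, PE, EP, ECO)
DEFAULT_VULNERABILITY = {1: 4.0, 2: 3.0, 3: 2.0, 4: 1.0}

LEVEL_NAMES = {1: "weaker", 2: "weak", 3: "medium", 4: "strong", 5: "stronger"}

_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def partition_grid(
    shape: tuple[int, int], cell_size: float, unit_size: float = 1000.0
) -> np.ndarray:
    """Assign every cell to a square evaluation unit.

    Returns an integer array of unit ids (row-major over unit blocks).
    Partial units at the right/bottom edge are kept as units of their own.
    """
    rows, cols = shape
    if rows == 0 or cols == 0:
        raise ValueError("empty raster")
    if unit_size <= 0 or cell_size <= 0:
        raise ValueError("unit and cell sizes must be positive")
    cells_per_unit = unit_size / cell_size
    r_idx = np.floor(np.arange(rows) / cells_per_unit).astype(int)
    c_idx = np.floor(np.arange(cols) / cells_per_unit).astype(int)
    n_unit_cols = c_idx[-1] + 1
    return r_idx[:, None] * n_unit_cols + c_idx[None, :]


def extract_patches(
    ple: Raster, unit_size: float = 1000.0, connectivity: int = 8
) -> pd.DataFrame:
    """Patch table: connected components of one PLE class within one unit.

    Patches are clipped at unit boundaries before measurement.  Area is
    cell count x cell area; perimeter counts every cell edge facing a
    different class, another unit, or nodata (equivalently
    ``4*a - 2*adjacencies`` within the clipped patch), times the cell size.

    Returns a DataFrame with columns unit, ple_class, cells, area_m2,
    perimeter_m.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    units = partition_grid(ple.shape, ple.cell_size, unit_size)
    records = []
    for uid in np.unique(units[ple.mask]):
        in_unit = units == uid
        rs, cs = np.where(in_unit)
        window = (slice(rs.min(), rs.max() + 1), slice(cs.min(), cs.max() + 1))
        sub = ple.data[window]
        for cls in PLE_CODES:
            binary = sub == cls
            if not binary.any():
                continue
            labels, n = ndimage.label(binary, structure=_STRUCTURES[connectivity])
            if n == 0:
                continue
            cells = np.bincount(labels.ravel(), minlength=n + 1)[1:]
            adj = np.zeros(n + 1, dtype=int)
            same_h = (labels[:, :-1] == labels[:, 1:]) & (labels[:, :-1] > 0)
            same_v = (labels[:-1, :] == labels[1:, :]) & (labels[:-1, :] > 0)
            np.add.at(adj, labels[:, :-1][same_h], 1)
            np.add.at(adj, labels[:-1, :][same_v], 1)
            perim_edges = 4 * cells - 2 * adj[1:]
            for a_cells, p_edges in zip(cells, perim_edges):
                records.append(
                    {
                        "unit": int(uid),
                        "ple_class": int(cls),
                        "cells": int(a_cells),
                        "area_m2": a_cells * ple.cell_area,
                        "perimeter_m": p_edges * ple.cell_size,
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["unit", "ple_class", "cells", "area_m2", "perimeter_m"]
    )


def sci(patches: pd.DataFrame, nominal_area: float) -> pd.Series:
    """Area-weighted mean patch fractal dimension per unit."""
    a = patches["area_m2"].to_numpy(dtype=float)
    p = patches["perimeter_m"].to_numpy(dtype=float)
    if np.any(a <= 1.0):
        raise ValueError("patch area <= 1 m^2 makes the fractal dimension singular")
    terms = 2.0 * np.log(0.25 * p) / np.log(a) * (a / nominal_area)
    return pd.Series(terms).groupby(patches["unit"].to_numpy()).sum()


def svi(
    patches: pd.DataFrame,
    nominal_area: float,
    weights: dict = DEFAULT_VULNERABILITY,
) -> pd.Series:
    """Area-weighted mean vulnerability per unit (nominal-area rule)."""
    missing = set(patches["ple_class"].unique()) - set(weights)
    if missing:
        raise ValueError(f"no vulnerability weight for class(es) {sorted(missing)}")
    f = patches["ple_class"].map(weights).to_numpy(dtype=float)
    contrib = f * patches["area_m2"].to_numpy(dtype=float) / nominal_area
    return pd.Series(contrib).groupby(patches["unit"].to_numpy()).sum()


def sri(patch_density: pd.Series) -> pd.Series:
    """Inverted min-max scaling of patch density over the units of one date."""
    lo, hi = patch_density.min(), patch_density.max()
    if hi == lo:
        log.info("degenerate patch-density pool (all %.3g); SRI set to 1", lo)
        return pd.Series(1.0, index=patch_density.index)
    return 1.0 - (patch_density - lo) / (hi - lo)


def conflict_units(
    ple: Raster,
    unit_size: float = 1000.0,
    connectivity: int = 8,
    weights: dict = DEFAULT_VULNERABILITY,
) -> pd.DataFrame:
    """Per-unit conflict table for one date: SCI, SVI, PD, SRI, raw SCCI,
    and the unit's area-dominant PLE class.

    Normalized SCCI and the five-level classification are added by
    :func:`normalize_scci`, which needs the whole pool of units.
    """
    patches = extract_patches(ple, unit_size=unit_size, connectivity=connectivity)
    if patches.empty:
        raise ValueError("no patches: raster is empty or all nodata")
    A = unit_size**2
    tab = pd.DataFrame(
        {
            "sci": sci(patches, A),
            "svi": svi(patches, A, weights),
            "n_patches": patches.groupby("unit").size(),
        }
    )
    tab.index.name = "unit"
    tab["pd"] = tab["n_patches"] / A
    tab["sri"] = sri(tab["pd"])
    tab["scci_raw"] = tab["sci"] + tab["svi"] - tab["sri"]
    dominant = (
        patches.groupby(["unit", "ple_class"])["area_m2"]
        .sum()
        .groupby(level="unit")
        .idxmax()
        .map(lambda t: t[1])
    )
    tab["dominant_ple"] = dominant
    units = partition_grid(ple.shape, ple.cell_size, unit_size)
    n_unit_cols = units[0, -1] + 1
    tab["unit_row"] = tab.index // n_unit_cols
    tab["unit_col"] = tab.index % n_unit_cols
    tab["centroid_x_m"] = (tab["unit_col"] + 0.5) * unit_size
    tab["centroid_y_m"] = (tab["unit_row"] + 0.5) * unit_size
    return tab


def scci_level(norm: np.ndarray) -> np.ndarray:
    """Equal-interval five-level cut of normalized SCCI: [0,0.2) -> 1, ...,
    [0.8,1.0] -> 5."""
    return np.minimum(np.floor(np.asarray(norm) * 5).astype(int) + 1, 5)


def normalize_scci(frames: dict, pool: str = "joint") -> dict:
    """Min-max normalize raw SCCI and assign conflict levels.

    ``frames`` maps date labels to the tables from :func:`conflict_units`.
    With ``pool='joint'`` (default) min and max are taken over all dates so
    levels are commensurable across years; ``pool='per-date'`` scales each
    date independently.
    """
    if pool not in ("joint", "per-date"):
        raise ValueError("pool must be 'joint' or 'per-date'")
    out = {}
    if pool == "joint":
        raw = np.concatenate([f["scci_raw"].to_numpy() for f in frames.values()])
        lo, hi = raw.min(), raw.max()
    for date, frame in frames.items():
        frame = frame.copy()
        if pool == "per-date":
            lo, hi = frame["scci_raw"].min(), frame["scci_raw"].max()
        if hi == lo:
            log.info("degenerate SCCI pool; normalized index set to 0")
            frame["scci_norm"] = 0.0
        else:
            frame["scci_norm"] = (frame["scci_raw"] - lo) / (hi - lo)
        frame["level"] = scci_level(frame["scci_norm"].to_numpy())
        out[date] = frame
    return out


def level_summary(units: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of units per conflict level (all 5 rows)."""
    counts = units["level"].value_counts().reindex(range(1, 6), fill_value=0)
    return pd.DataFrame(
        {
            "level": counts.index,
            "name": [LEVEL_NAMES[i] for i in counts.index],
            "count": counts.to_numpy(),
            "percent": 100.0 * counts.to_numpy() / len(units),
        }
    ).set_index("level")


def level_by_ple_summary(units: pd.DataFrame) -> pd.DataFrame:
    """Cross-tab of conflict level by area-dominant PLE space, as percent of
    all units."""
    tab = pd.crosstab(units["dominant_ple"], units["level"])
    tab = tab.reindex(index=PLE_CODES, columns=range(1, 6), fill_value=0)
    tab.index = [PLE_NAMES[c] for c in tab.index]
    return 100.0 * tab / len(units)


def level_raster(units: pd.DataFrame, unit_size: float = 1000.0) -> Raster:
    """Render per-unit conflict levels as a coarse raster (one cell per
    unit)."""
    rows = int(units["unit_row"].max()) + 1
    cols = int(units["unit_col"].max()) + 1
    grid = np.zeros((rows, cols), dtype=np.uint8)
    grid[units["unit_row"].to_numpy(), units["unit_col"].to_numpy()] = units[
        "level"
    ].to_numpy()
    return Raster(grid, cell_size=unit_size)
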