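"""Reclassification of land use into production-living-ecological (PLE)
space and the area / change / proportion bookkeeping built on it.

The four PLE spaces re-partition the six primary land-use classes by
dominant function: construction land is "living-production" (LP), cultivated
land is "production-ecological" (PE, farming with secondary ecological
services), woodland and water are "ecological-production" (EP, ecosystems
with secondary production), and unused land is ecological (ECO).  Where
grassland sits at the 6-class level is genuinely ambiguous — a barren-
grassland reading puts it in ECO, an agro-pastoral reading in PE; both
mappings ship, with PE the default (see ``TABLE1_MAPPING`` for the
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import LAND_USE_CODES, LAND_USE_NAMES, PLE_CODES, PLE_NAMES, Raster

LP, PE, EP, ECO = PLE_CODES


@dataclass(frozen=True)
class PLEMapping:
    """Total map from land-use class code to PLE space code."""

    table: dict

    def __post_init__(self) -> None:
        bad = set(self.table.values()) - set(PLE_CODES)
        if bad:
            raise ValueError(f"mapping targets outside PLE codes: {bad}")

    def __getitem__(self, code: int) -> int:
        return self.table[code]

    def lookup_array(self, max_code: int = 6) -> np.ndarray:
        """Vectorized lookup table; index 0 (nodata) maps to 0."""
        arr = np.zeros(max_code + 1, dtype=np.uint8)
        for code, ple in self.table.items():
            arr[code] = ple
        return arr


#: default mapping: grassland counts toward production-ecological space
DEFAULT_MAPPING = PLEMapping({1: PE, 2: EP, 3: PE, 4: EP, 5: LP, 6: ECO})

#: alternative following the secondary-legend reading (barren grassland is
#: ecological space)
TABLE1_MAPPING = PLEMapping({1: PE, 2: EP, 3: ECO, 4: EP, 5: LP, 6: ECO})


def classify_ple(lu: Raster, mapping: PLEMapping = DEFAULT_MAPPING) -> Raster:
    """Per-cell recode of a land-use raster into the four PLE spaces.

    Nodata cells are preserved.  Raises if the raster contains a class code
    the mapping does not cover.
    """
    present = {int(c) for c in np.unique(lu.data)} - {lu.nodata}
    unmapped = present - set(mapping.table)
    if unmapped:
        raise ValueError(f"land-use code(s) {sorted(unmapped)} missing from PLE mapping")
    lut = mapping.lookup_array(max(int(max(present, default=0)), 6))
    out = lut[lu.data]
    return Raster(out, cell_size=lu.cell_size, nodata=lu.nodata, meta=dict(lu.meta))


def aggregate_areas(areas_by_class: dict, mapping: PLEMapping = DEFAULT_MAPPING) -> dict:
    """Sum per-land-use areas into per-PLE-space areas.

    Because :func:`classify_ple` is a pure per-cell recode, PLE areas are
    exactly the sums of the constituent land-use areas; this helper performs
    that composition on any area table (km2 or cell counts).
    """
    out = {code: 0.0 for code in PLE_CODES}
    for code, area in areas_by_class.items():
        out[mapping[code]] += area
    return out


def _area_frame(rasters: dict, codes, names) -> pd.DataFrame:
    frames = {}
    for date, raster in rasters.items():
        frames[date] = raster.class_counts(codes) * raster.cell_area / 1e6
    tab = pd.DataFrame(frames, index=[names[c] for c in codes]).T
    tab.index.name = "date"
    return tab


def area_table(rasters: dict, kind: str = "landuse") -> pd.DataFrame:
    """Per-date class areas in km2 for dated rasters of equal geometry.

    ``rasters`` maps a sortable date label to a :class:`Raster`; ``kind``
    selects the land-use (6-class) or PLE (4-class) legend.
    """
    if not rasters:
        raise ValueError("need at least one raster")
    items = sorted(rasters.items())
    first = items[0][1]
    for _, r in items[1:]:
        if not first.same_geometry(r):
            raise ValueError("rasters must share geometry")
    codes, names = (
        (LAND_USE_CODES, LAND_USE_NAMES) if kind == "landuse" else (PLE_CODES, PLE_NAMES)
    )
    return _area_frame(dict(items), codes, names)


def change_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Interval changes (km2) and rates (%) from a per-date area table.

    For each consecutive pair of dates and for the first-to-last interval:
    change = later − earlier, rate = 100 × change / earlier.  The rate is
    NaN when the earlier area is zero (undefined base).
    """
    dates = list(areas.index)
    intervals = list(zip(dates[:-1], dates[1:]))
    if len(dates) > 2:
        intervals.append((dates[0], dates[-1]))
    rows = {}
    for a, b in intervals:
        change = areas.loc[b] - areas.loc[a]
        base = areas.loc[a]
        rate = 100.0 * change / base.where(base != 0)
        rows[f"{a}-{b} change"] = change
        rows[f"{a}-{b} rate %"] = rate
    return pd.DataFrame(rows).T


def proportion_table(areas: pd.DataFrame) -> pd.DataFrame:
    """Per-date percentage share of each class in the total area."""
    totals = areas.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero total area")
    return 100.0 * areas.div(totals, axis=0)
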