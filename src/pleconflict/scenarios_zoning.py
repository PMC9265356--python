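"""Built-in simulation scenarios and conflict-transition functional zoning.

Three planning scenarios are shipped as ready-made configurations:

* **ND** (natural development) — economic priority: every class may convert
  to construction land, construction never converts away.
* **CL** (cultivated-land protection) — food security: conversion rules
  favour keeping and regaining cultivated land, with basic farmland as a
  hard restriction.
* **EP** (ecological protection) — ecological priority: woodland and
  grassland accept no losses, other classes may still feed cultivated or
  construction land to keep food and growth viable.

Each scenario carries a 6x6 binary allowance matrix (1 = conversion
permitted; rows are source classes in the order cultivated, woodland,
grassland, water, construction, unused), per-class neighborhood weights
expressing expansion strength, and a demand vector in km2.

Zoning compares conflict levels at two dates per evaluation unit.  The
two-digit transition code ``10*level_t1 + level_t2`` is mapped onto five
functional zones (ecological protection, ecological conservation, modern
agricultural, development coordination, urban optimization); codes outside
the 15 canonical ones fall back on the end-state level (configurable to
strict ``unassigned``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import LAND_USE_NAMES

#: Table-9-style neighborhood expansion weights, one per land-use class
NEIGHBORHOOD_WEIGHTS = (0.56, 0.25, 0.36, 0.43, 1.0, 0.25)


@dataclass
class ScenarioSpec:
    """One planning scenario: allowance matrix, neighborhood weights,
    demand (km2) and an optional restriction-mask reference."""

    name: str
    allowance: np.ndarray
    neighborhood_weights: tuple = NEIGHBORHOOD_WEIGHTS
    demand_km2: np.ndarray | None = None
    restriction: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.allowance = np.asarray(self.allowance, dtype=int)
        if self.allowance.shape != (6, 6) or not np.isin(self.allowance, (0, 1)).all():
            raise ValueError("allowance must be a 6x6 binary matrix")
        if np.any(np.diag(self.allowance) != 1):
            raise ValueError("allowance diagonal must be 1")
        w = np.asarray(self.neighborhood_weights, dtype=float)
        if w.shape != (6,) or np.any((w < 0) | (w > 1)):
            raise ValueError("neighborhood weights must be 6 values in [0, 1]")
        if self.demand_km2 is not None:
            self.demand_km2 = np.asarray(self.demand_km2, dtype=float)


_ND_ALLOWANCE = [
    [1, 1, 1, 0, 1, 0],
    [1, 1, 1, 0, 1, 1],
    [1, 1, 1, 0, 1, 1],
    [0, 0, 0, 1, 1, 1],
    [0, 0, 0, 0, 1, 0],
    [1, 1, 1, 0, 1, 1],
]

_CL_ALLOWANCE = [
    [1, 1, 1, 0, 1, 1],
    [1, 1, 1, 0, 1, 1],
    [1, 1, 1, 0, 1, 1],
    [0, 0, 0, 1, 0, 1],
    [0, 0, 0, 0, 1, 0],
    [1, 1, 1, 0, 1, 1],
]

_EP_ALLOWANCE = [
    [1, 1, 1, 0, 1, 0],
    [0, 1, 0, 0, 0, 0],
    [0, 0, 1, 0, 0, 0],
    [0, 0, 0, 1, 0, 1],
    [0, 1, 1, 0, 1, 0],
    [1, 1, 1, 0, 1, 1],
]

#: demand forecasts (km2) per scenario, in land-use class order
_DEMANDS = {
    "ND": (1453.65, 37.67, 0.15, 225.29, 297.63, 2.24),
    "EP": (1458.42, 38.13, 0.15, 226.10, 291.59, 2.24),
    "CL": (1467.38, 33.24, 0.15, 225.51, 288.12, 2.24),
}


def builtin_scenarios() -> dict:
    """The three shipped scenario specifications, keyed ND / CL / EP."""
    return {
        "ND": ScenarioSpec(
            "ND",
            _ND_ALLOWANCE,
            demand_km2=np.array(_DEMANDS["ND"]),
            description="natural development: economic benefit priority",
        ),
        "CL": ScenarioSpec(
            "CL",
            _CL_ALLOWANCE,
            demand_km2=np.array(_DEMANDS["CL"]),
            restriction="basic_farmland",
            description="cultivated-land protection: food security priority",
        ),
        "EP": ScenarioSpec(
            "EP",
            _EP_ALLOWANCE,
            demand_km2=np.array(_DEMANDS["EP"]),
            restriction="ecological_reserve",
            description="ecological protection: ecological benefit priority",
        ),
    }


def scenario_to_dict(spec: ScenarioSpec) -> dict:
    """YAML-friendly representation of a scenario."""
    return {
        "name": spec.name,
        "description": spec.description,
        "allowance": spec.allowance.tolist(),
        "classes": [LAND_USE_NAMES[c] for c in range(1, 7)],
        "neighborhood_weights": list(spec.neighborhood_weights),
        "demand_km2": None if spec.demand_km2 is None else spec.demand_km2.tolist(),
        "restriction": spec.restriction,
    }


def scenario_from_dict(d: dict) -> ScenarioSpec:
    return ScenarioSpec(
        name=d["name"],
        allowance=np.asarray(d["allowance"]),
        neighborhood_weights=tuple(d.get("neighborhood_weights", NEIGHBORHOOD_WEIGHTS)),
        demand_km2=None if d.get("demand_km2") is None else np.asarray(d["demand_km2"]),
        restriction=d.get("restriction"),
        description=d.get("description", ""),
    )


# ---------------------------------------------------------------------------
# Conflict-transition zoning
# ---------------------------------------------------------------------------

ZONE_NAMES = (
    "ecological protection",
    "ecological conservation",
    "modern agricultural",
    "development coordination",
    "urban optimization",
)

#: canonical transition-code -> zone mapping
ZONE_CODES = {
    "ecological protection": (11, 21, 41),
    "ecological conservation": (22, 32, 42),
    "modern agricultural": (13, 23, 33),
    "development coordination": (43, 34, 44),
    "urban optimization": (45, 54, 55),
}

_CODE_TO_ZONE = {
    code: zone for zone, codes in ZONE_CODES.items() for code in codes
}

#: fallback by end-state conflict level for the ten codes the canonical
#: table omits
_FALLBACK_BY_END_LEVEL = {
    1: "ecological conservation",
    2: "ecological conservation",
    3: "modern agricultural",
    4: "development coordination",
    5: "urban optimization",
}


def transition_codes(levels_t1: pd.Series, levels_t2: pd.Series) -> pd.DataFrame:
    """Two-digit conflict-level transition code per unit, plus flags.

    Units missing a level at either date are flagged and excluded from the
    count matrix.
    """
    units = levels_t1.index.union(levels_t2.index)
    l1 = levels_t1.reindex(units)
    l2 = levels_t2.reindex(units)
    ok = l1.notna() & l2.notna()
    codes = pd.Series(np.nan, index=units, name="code")
    codes[ok] = 10 * l1[ok].astype(int) + l2[ok].astype(int)
    bad = codes.dropna()[(codes.dropna() < 11) | (codes.dropna() > 55)]
    if len(bad):
        raise ValueError(f"conflict levels outside 1..5 produced codes {sorted(bad)}")
    return pd.DataFrame({"code": codes, "defined": ok})


def transition_count_matrix(codes: pd.DataFrame) -> pd.DataFrame:
    """5x5 matrix of unit counts, rows = level at t1, columns = level at t2."""
    mat = pd.DataFrame(0, index=range(1, 6), columns=range(1, 6))
    valid = codes.loc[codes["defined"], "code"].astype(int)
    for code, n in valid.value_counts().items():
        mat.loc[code // 10, code % 10] += n
    return mat


def assign_zones(codes: pd.DataFrame, fallback: str = "end-level") -> pd.DataFrame:
    """Map transition codes to the five functional zones.

    The 15 canonical codes map directly; the rest use the end-state-level
    fallback (or ``'unassigned'`` for strict behaviour).  The returned frame
    has columns ``zone`` and ``fallback_used``.
    """
    if fallback not in ("end-level", "unassigned"):
        raise ValueError("fallback must be 'end-level' or 'unassigned'")
    zones, used_fallback = [], []
    for _, row in codes.iterrows():
        if not row["defined"]:
            zones.append("unassigned")
            used_fallback.append(False)
            continue
        code = int(row["code"])
        if code in _CODE_TO_ZONE:
            zones.append(_CODE_TO_ZONE[code])
            used_fallback.append(False)
        elif fallback == "end-level":
            zones.append(_FALLBACK_BY_END_LEVEL[code % 10])
            used_fallback.append(True)
        else:
            zones.append("unassigned")
            used_fallback.append(True)
    return pd.DataFrame(
        {"code": codes["code"], "zone": zones, "fallback_used": used_fallback},
        index=codes.index,
    )


def zone_summary(zones: pd.DataFrame, unit_area_km2: float = 1.0) -> pd.DataFrame:
    """Unit counts, areas and percentages per functional zone."""
    order = list(ZONE_NAMES) + ["unassigned"]
    counts = zones["zone"].value_counts().reindex(order, fill_value=0)
    counts = counts[counts.index.isin(ZONE_NAMES) | (counts > 0)]
    tab = pd.DataFrame(
        {
            "units": counts,
            "area_km2": counts * unit_area_km2,
            "percent": 100.0 * counts / len(zones),
            "fallback_units": zones.groupby("zone")["fallback_used"]
            .sum()
            .reindex(counts.index, fill_value=0)
            .astype(int),
        }
    )
    tab.index.name = "zone"
    return tab
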