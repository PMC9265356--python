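"""Synthetic landscape generator: autocorrelated land-use rasters, paired
dates with a known transition structure, and driver surfaces.

The generator emulates the kind of inputs a county-scale land-use conflict
study works from: a categorical raster of six primary classes (cultivated,
woodland, grassland, water, construction, unused) dominated by cultivated
land, a stack of continuous driver surfaces (terrain, climate, socio-economic
proxies, accessibility distances), and a second-date raster produced by a
known row-stochastic transition matrix.  Because class placement is a
monotone function of the drivers, a suitability model trained on the output
is learnable by construction, which is what makes the downstream simulation
testable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import Raster

#: class shares mirroring the dominant-cultivated structure of a Jianghan
#: Plain county circa 2000 (cultivated, woodland, grassland, water,
#: construction, unused)
DEFAULT_PROPORTIONS = (0.770, 0.013, 0.001, 0.095, 0.116, 0.005)


def default_transition() -> np.ndarray:
    """A mostly-diagonal transition matrix of realistic magnitude.

    Cultivated land leaks to construction and water (urbanisation and
    aquaculture conversion), small classes churn a little; every row sums
    to 1.
    """
    P = np.eye(6)
    leak = {
        (0, 4): 0.020,  # cultivated -> construction
        (0, 3): 0.008,  # cultivated -> water
        (1, 0): 0.030,  # woodland -> cultivated
        (2, 0): 0.100,  # grassland -> cultivated
        (3, 0): 0.010,  # water -> cultivated
        (5, 0): 0.100,  # unused -> cultivated
        (5, 3): 0.050,  # unused -> water
    }
    for (a, b), p in leak.items():
        P[a, b] = p
        P[a, a] -= p
    return P


@dataclass
class SynthConfig:
    """Configuration for one synthetic landscape.

    ``autocorrelation_range`` is the Gaussian smoothing sigma, in cells,
    applied to the white-noise fields from which drivers and class scores
    are built; it controls patch size.
    """

    grid_shape: tuple[int, int] = (200, 200)
    cell_size_m: float = 30.0
    class_proportions: tuple = DEFAULT_PROPORTIONS
    autocorrelation_range: float = 8.0
    true_transition: np.ndarray = field(default_factory=default_transition)
    driver_count: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (6,):
            raise ValueError("class_proportions must have 6 entries")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {props.sum()}")
        if np.any(props < 0):
            raise ValueError("class_proportions must be non-negative")
        P = np.asarray(self.true_transition, dtype=float)
        if P.shape != (6, 6) or np.any(P < 0):
            raise ValueError("true_transition must be a non-negative 6x6 matrix")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("true_transition rows must sum to 1")
        if self.driver_count < 1:
            raise ValueError("driver_count must be >= 1")
        self.class_proportions = tuple(props)
        self.true_transition = P


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed white noise."""
    field = rng.standard_normal(shape)
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def gen_drivers(cfg: SynthConfig) -> np.ndarray:
    """Generate a ``(driver_count, rows, cols)`` stack of driver surfaces.

    Each layer is Gaussian-smoothed white noise (sigma =
    ``autocorrelation_range``); every other layer additionally carries a
    monotone linear gradient, mimicking large-scale trends such as elevation
    or distance-to-city.  Layers are standardized to mean 0, sd 1.
    """
    rng = np.random.default_rng(cfg.seed)
    rows, cols = cfg.grid_shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    layers = []
    for d in range(cfg.driver_count):
        layer = _smooth_field(rng, cfg.grid_shape, cfg.autocorrelation_range)
        if d % 2 == 1:
            # alternate gradient orientations so drivers are not collinear
            gradient = (yy if d % 4 == 1 else xx).astype(float)
            gradient = (gradient - gradient.mean()) / max(gradient.std(), 1e-12)
            layer = layer + 0.5 * gradient
        layer -= layer.mean()
        layer /= layer.std()
        layers.append(layer)
    return np.stack(layers)


def class_scores(cfg: SynthConfig, drivers: np.ndarray) -> np.ndarray:
    """Per-class affinity surfaces: a fixed linear combination of drivers
    plus a little smoothed noise.

    The weight matrix is drawn once from ``cfg.seed`` so that the same
    configuration always scores cells identically; the noise keeps class
    boundaries from being perfectly sharp while leaving the class map a
    learnable function of the drivers.
    """
    rng = np.random.default_rng((cfg.seed, 0xC1A55))
    K = 6
    weights = rng.normal(size=(K, drivers.shape[0]))
    weights /= np.linalg.norm(weights, axis=1, keepdims=True)
    scores = np.tensordot(weights, drivers, axes=(1, 0))
    for k in range(K):
        scores[k] += 0.3 * _smooth_field(rng, cfg.grid_shape, cfg.autocorrelation_range)
    return scores


def _largest_remainder(total: int, fractions: np.ndarray) -> np.ndarray:
    """Integer apportionment of ``total`` by ``fractions`` (sum preserved)."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts))
        counts[order[:short]] += 1
    return counts


def gen_landuse(cfg: SynthConfig, drivers: np.ndarray | None = None) -> Raster:
    """Generate a categorical land-use raster hitting the configured class
    proportions exactly (up to integer rounding).

    Cells are assigned by rank-thresholding: classes are processed from the
    rarest to the most abundant, each claiming its quota of the unassigned
    cells with the highest affinity for it.  Rare classes pick first so that
    they are not swallowed by the dominant class's quota.
    """
    if drivers is None:
        drivers = gen_drivers(cfg)
    if drivers.shape[1:] != tuple(cfg.grid_shape):
        raise ValueError(
            f"driver shape {drivers.shape[1:]} does not match grid {cfg.grid_shape}"
        )
    scores = class_scores(cfg, drivers)
    props = np.asarray(cfg.class_proportions)
    rows, cols = cfg.grid_shape
    n = rows * cols
    quotas = _largest_remainder(n, props)
    flat_scores = scores.reshape(6, n)
    assigned = np.zeros(n, dtype=np.uint8)
    order = np.argsort(props, kind="stable")  # rarest classes claim cells first
    for k in order:
        if quotas[k] == 0:
            continue
        free = np.flatnonzero(assigned == 0)
        top = free[np.argsort(-flat_scores[k, free], kind="stable")[: quotas[k]]]
        assigned[top] = k + 1
    lu = assigned.reshape(rows, cols)
    return Raster(
        lu,
        cell_size=cfg.cell_size_m,
        meta={"seed": cfg.seed, "class_proportions": list(props)},
    )


def evolve_landuse(
    lu: Raster,
    P: np.ndarray,
    cfg: SynthConfig,
    drivers: np.ndarray | None = None,
    seed: int | None = None,
) -> Raster:
    """Produce a second-date raster whose cell transitions follow ``P``.

    Within each source class, the number of cells converting to each target
    class is the largest-remainder apportionment of the row ``P[c, :]``, so
    empirical transition frequencies match ``P`` up to rounding.  Converting
    cells are chosen preferentially where the target class's affinity score
    is highest (plus a small seeded jitter for tie-breaking), which gives the
    conversions spatial structure instead of salt-and-pepper noise.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (6, 6):
        raise ValueError("transition matrix must be 6x6")
    if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("transition matrix rows must sum to 1")
    if drivers is None:
        drivers = gen_drivers(cfg)
    if drivers.shape[1:] != lu.shape:
        raise ValueError("driver shape does not match raster")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    scores = class_scores(cfg, drivers).reshape(6, -1)
    jitter = rng.normal(scale=1e-6, size=scores.shape[1])
    flat = lu.data.ravel()
    out = flat.copy()
    for c in range(6):
        cells = np.flatnonzero(flat == c + 1)
        if cells.size == 0:
            continue
        quotas = _largest_remainder(cells.size, P[c])
        # allocate off-diagonal targets by descending affinity; the source
        # class keeps the remainder
        remaining = cells.copy()
        targets = [k for k in range(6) if k != c and quotas[k] > 0]
        targets.sort(key=lambda k: -P[c, k])
        for k in targets:
            pref = np.argsort(-(scores[k, remaining] + jitter[remaining]), kind="stable")
            chosen = remaining[pref[: quotas[k]]]
            out[chosen] = k + 1
            remaining = np.setdiff1d(remaining, chosen, assume_unique=True)
    evolved = Raster(
        out.reshape(lu.shape),
        cell_size=lu.cell_size,
        meta={
            "seed": cfg.seed if seed is None else seed,
            "true_transition": P.tolist(),
        },
    )
    return evolved


def empirical_transition(lu_t1: Raster, lu_t2: Raster) -> np.ndarray:
    """Row-normalized cell-transition frequencies between two dates.

    Empty source rows are returned as identity rows.
    """
    if not lu_t1.same_geometry(lu_t2):
        raise ValueError("rasters must share geometry")
    a, b = lu_t1.data.ravel(), lu_t2.data.ravel()
    valid = (a != lu_t1.nodata) & (b != lu_t2.nodata)
    counts = np.zeros((6, 6))
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    rows = counts.sum(axis=1, keepdims=True)
    P = np.where(rows > 0, counts / np.maximum(rows, 1), 0.0)
    for c in np.flatnonzero(rows.ravel() == 0):
        P[c, c] = 1.0
    return P
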