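"""Future land-use simulation core: Markov demand projection, neural-network
suitability surfaces, and cellular-automata allocation with adaptive
inertia, neighborhood effects and conversion constraints.

The simulation splits into a quantity model and an allocation model.  The
quantity model is a first-order Markov chain on class areas: the transition
probability matrix fitted over a calibration interval is applied to the
base-date state vector to obtain per-class demand at the horizon.  The
allocation model places that demand on the grid cell by cell.  Each cell's
conversion probability to class ``k`` multiplies four factors:

    TProb[p, k] = sp[p, k] * Omega[p, k] * Inertia[k] * M[c(p), k]

where ``sp`` is the suitability probability from a one-hidden-layer neural
network trained on driver surfaces, ``Omega`` is the Moore-neighborhood
density of class ``k`` scaled by a per-class weight, ``Inertia`` is an
adaptive per-class multiplier steered by the running demand gap, and ``M``
is the scenario's binary allowance matrix (1 = conversion permitted), the
multiplicative complement of a conversion cost.  Cells are visited in
descending order of conversion probability; a conversion happens only while
the source class is above its demand and the target below.  Restricted
cells (e.g. basic farmland, ecological reserves) never change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import cohen_kappa_score
from sklearn.neural_network import MLPClassifier

from .raster import LAND_USE_CODES, Raster

log = logging.getLogger(__name__)

K = len(LAND_USE_CODES)


# ---------------------------------------------------------------------------
# Markov demand
# ---------------------------------------------------------------------------


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition matrix over a calibration interval."""

    P: np.ndarray
    interval_years: float = 1.0

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(self.P < 0):
            raise ValueError("transition probabilities must be non-negative")
        if np.max(np.abs(self.P.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")


def fit_markov(
    lu_t1: Raster, lu_t2: Raster, interval_years: float = 1.0
) -> TransitionMatrix:
    """Fit the cell-transition probability matrix between two dated rasters.

    ``P[a, b]`` is the fraction of class-``a`` cells at t1 found as class
    ``b`` at t2.  Source classes absent at t1 get an identity row (logged).
    """
    if not lu_t1.same_geometry(lu_t2):
        raise ValueError("rasters must share geometry")
    a, b = lu_t1.data.ravel(), lu_t2.data.ravel()
    valid = (a != lu_t1.nodata) & (b != lu_t2.nodata)
    counts = np.zeros((K, K))
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    rows = counts.sum(axis=1)
    P = np.zeros_like(counts)
    for c in range(K):
        if rows[c] > 0:
            P[c] = counts[c] / rows[c]
        else:
            P[c, c] = 1.0
            log.info("class %d absent at t1; identity row assumed", c + 1)
    return TransitionMatrix(P, interval_years)


def project_demand(
    tm: TransitionMatrix, state: np.ndarray, horizon_years: float
) -> np.ndarray:
    """Markov projection of the class state vector to the horizon.

    The horizon must be a positive multiple of the calibration interval;
    the state is advanced by ``P^T`` once per interval.  Total quantity is
    conserved exactly.
    """
    steps = horizon_years / tm.interval_years
    if steps <= 0 or abs(steps - round(steps)) > 1e-9:
        raise ValueError(
            f"horizon {horizon_years} is not a positive multiple of the "
            f"calibration interval {tm.interval_years}; re-calibrate or use "
            "the nearest multiple"
        )
    state = np.asarray(state, dtype=float)
    out = np.linalg.matrix_power(tm.P.T, int(round(steps))) @ state
    return out


# ---------------------------------------------------------------------------
# Suitability (ANN)
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityModel:
    """Trained suitability classifier plus the class codes it knows."""

    model: MLPClassifier
    codes: np.ndarray

    def predict(self, drivers: np.ndarray) -> np.ndarray:
        """Per-cell suitability probabilities, shape (rows, cols, K).

        Probabilities over the six classes sum to 1 per cell (classes unseen
        in training have probability 0).
        """
        rows, cols = drivers.shape[1:]
        X = drivers.reshape(drivers.shape[0], -1).T
        proba = self.model.predict_proba(X)
        sp = np.zeros((rows * cols, K))
        sp[:, self.codes - 1] = proba
        sp /= sp.sum(axis=1, keepdims=True)
        return sp.reshape(rows, cols, K)


def train_suitability(
    lu: Raster,
    drivers: np.ndarray,
    sample_n: int | None = None,
    seed: int = 0,
    hidden: int = 12,
) -> SuitabilityModel:
    """Train a one-hidden-layer neural classifier of class given drivers.

    Cells are sampled uniformly at random (default 5% of the grid, at least
    1000); if a class present on the raster is missing from the sample, the
    sample is topped up with a stratified draw from that class.
    """
    rows, cols = lu.shape
    n_cells = rows * cols
    if sample_n is None:
        sample_n = max(1000, n_cells // 20)
    if sample_n > n_cells:
        raise ValueError("sample_n exceeds cell count")
    rng = np.random.default_rng(seed)
    flat = lu.data.ravel()
    valid = np.flatnonzero(flat != lu.nodata)
    idx = rng.choice(valid, size=min(sample_n, valid.size), replace=False)
    present = np.unique(flat[valid])
    sampled = set(np.unique(flat[idx]))
    for cls in present:
        if cls not in sampled:
            pool = np.flatnonzero(flat == cls)
            extra = rng.choice(pool, size=min(20, pool.size), replace=False)
            idx = np.concatenate([idx, extra])
    X = drivers.reshape(drivers.shape[0], -1).T[idx]
    y = flat[idx]
    model = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        max_iter=500,
        random_state=int(rng.integers(2**31 - 1)),
    )
    model.fit(X, y)
    return SuitabilityModel(model=model, codes=np.asarray(model.classes_, dtype=int))


# ---------------------------------------------------------------------------
# CA allocation
# ---------------------------------------------------------------------------


def neighborhood_effect(
    lu: Raster, k: int, window: int = 3, weight: float = 1.0
) -> np.ndarray:
    """Moore-neighborhood density of class ``k`` around every cell.

    Counts class-``k`` cells in the ``window x window`` box excluding the
    center, divides by ``window**2 - 1`` and scales by the per-class
    neighborhood weight.  Edge cells use the truncated window with the same
    denominator.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    kernel = np.ones((window, window))
    kernel[window // 2, window // 2] = 0.0
    indicator = (lu.data == k).astype(float)
    counts = ndimage.convolve(indicator, kernel, mode="constant", cval=0.0)
    return counts / (window**2 - 1) * weight


def update_inertia(
    inertia: np.ndarray,
    gap_prev2: np.ndarray,
    gap_prev1: np.ndarray,
    convention: str = "printed",
) -> np.ndarray:
    """Adaptive per-class inertia update from the last two demand gaps.

    Gaps are signed ``demand - current count``.  Under the ``printed``
    convention the multiplier cases are keyed on the signed gaps:
    unchanged when ``gap(t-2) <= gap(t-1)``; times ``gap(t-2)/gap(t-1)``
    when ``0 > gap(t-2) > gap(t-1)``; times ``gap(t-1)/gap(t-2)`` when
    ``gap(t-1) > gap(t-2) > 0``.  The ``absolute`` convention keys the same
    multipliers on the absolute gap growing, so inertia always ratchets up
    when allocation is falling behind demand.  A zero denominator gap is
    treated as converged (no change).
    """
    if convention not in ("printed", "absolute"):
        raise ValueError("convention must be 'printed' or 'absolute'")
    inertia = np.asarray(inertia, dtype=float).copy()
    d2 = np.asarray(gap_prev2, dtype=float)
    d1 = np.asarray(gap_prev1, dtype=float)
    for k in range(inertia.size):
        if d1[k] == 0 or d2[k] == 0:
            continue
        if convention == "printed":
            if 0 > d2[k] > d1[k]:
                inertia[k] *= d2[k] / d1[k]
            elif d1[k] > d2[k] > 0:
                inertia[k] *= d1[k] / d2[k]
        else:
            if abs(d1[k]) > abs(d2[k]):
                if d1[k] < 0:
                    inertia[k] *= d2[k] / d1[k]
                else:
                    inertia[k] *= d1[k] / d2[k]
    return inertia


@dataclass
class AllocationResult:
    """Final raster plus the per-iteration trace of the CA run."""

    landuse: Raster
    converged: bool
    iterations: int
    final_counts: np.ndarray
    demand_cells: np.ndarray
    residual: np.ndarray
    history: list = field(default_factory=list)


def demand_km2_to_cells(demand_km2: np.ndarray, lu: Raster) -> np.ndarray:
    """Convert a km2 demand vector to whole cells conserving the total.

    Rounds by largest remainder so the cell total equals the number of data
    cells exactly.
    """
    demand_km2 = np.asarray(demand_km2, dtype=float)
    total_cells = int(lu.mask.sum())
    frac = demand_km2 / demand_km2.sum()
    raw = frac * total_cells
    cells = np.floor(raw).astype(int)
    short = total_cells - cells.sum()
    order = np.argsort(-(raw - cells))
    cells[order[:short]] += 1
    return cells


def allocate(
    lu: Raster,
    suitability: np.ndarray,
    demand_cells: np.ndarray,
    allowance: np.ndarray,
    neighborhood_weights: np.ndarray,
    restriction: np.ndarray | None = None,
    window: int = 3,
    max_iter: int = 300,
    tol_fraction: float = 0.005,
    tol_cells: int = 10,
    omega_floor: float = 0.01,
    inertia_convention: str = "printed",
    seed: int = 0,
) -> AllocationResult:
    """Iterative CA allocation of per-class demand on the grid.

    Per iteration: compute conversion probabilities, visit candidate cells
    in descending order of their best conversion probability, and convert a
    cell to its best under-demand class while its current class is over
    demand.  Inertia is adapted from the running demand gaps.  Stops when
    every class count is within ``max(tol_fraction * demand, tol_cells)``
    of demand, or after ``max_iter`` sweeps (the unmet residual per class is
    reported either way).

    ``omega_floor`` puts a small lower bound on the neighborhood factor used
    inside the conversion probability, so a class whose demand is unmet can
    still seed a patch where it has no neighbors yet; the strictly
    multiplicative form would otherwise deadlock whenever the only donor
    cells lie outside every existing patch's reach.  Forbidden transitions
    and restricted cells are unaffected.
    """
    demand_cells = np.asarray(demand_cells, dtype=int)
    allowance = np.asarray(allowance)
    if allowance.shape != (K, K):
        raise ValueError("allowance matrix must be 6x6")
    if np.any(np.diag(allowance) != 1):
        raise ValueError("allowance diagonal must be 1 (a class may keep itself)")
    weights = np.asarray(neighborhood_weights, dtype=float)
    rows, cols = lu.shape
    mask = lu.mask
    if restriction is None:
        restriction = np.zeros(lu.shape, dtype=bool)
    if int(demand_cells.sum()) != int(mask.sum()):
        raise ValueError("demand cells must sum to the number of data cells")
    rng = np.random.default_rng(seed)
    current = lu.data.copy()
    tol = np.maximum((tol_fraction * demand_cells).astype(int), tol_cells)
    inertia = np.ones(K)
    gaps: list[np.ndarray] = []
    history = []
    converged = False
    it = 0
    sp_flat = suitability.reshape(-1, K)
    mutable = (mask & ~restriction).ravel()
    for it in range(1, max_iter + 1):
        state = Raster(current, cell_size=lu.cell_size, nodata=lu.nodata)
        counts = state.class_counts()
        gap = demand_cells - counts
        if np.all(np.abs(gap) <= tol):
            converged = True
            history.append(
                {"iteration": it, "gap": gap.copy(), "inertia": inertia.copy()}
            )
            break
        if len(gaps) >= 2:
            inertia = update_inertia(inertia, gaps[-2], gaps[-1], inertia_convention)
        gaps.append(gap)
        omega = np.stack(
            [
                neighborhood_effect(state, k + 1, window, weights[k])
                for k in range(K)
            ],
            axis=-1,
        ).reshape(-1, K)
        omega = np.maximum(omega, omega_floor)
        cur_flat = current.ravel()
        allow = allowance[cur_flat - 1]  # (cells, K); nodata rows unused
        tprob = sp_flat * omega * inertia[None, :] * allow
        # tiny seeded jitter breaks ties deterministically; zero (forbidden or
        # unreachable) probabilities stay exactly zero
        jitter = rng.uniform(0, 1e-12, size=tprob.shape)
        tprob = np.where(tprob > 0, tprob + jitter, 0.0)
        over = counts > demand_cells
        under = counts < demand_cells
        src_over = over[cur_flat - 1] & mutable
        cand_prob = np.where(under[None, :], tprob, -np.inf)
        cand_prob[np.arange(cand_prob.shape[0]), cur_flat - 1] = -np.inf
        best_k = np.argmax(cand_prob, axis=1)
        best_p = cand_prob[np.arange(cand_prob.shape[0]), best_k]
        candidates = np.flatnonzero(src_over & (best_p > 0))
        if candidates.size == 0:
            history.append(
                {"iteration": it, "gap": gap.copy(), "inertia": inertia.copy()}
            )
            break
        order = candidates[np.argsort(-best_p[candidates], kind="stable")]
        surplus = np.maximum(counts - demand_cells, 0)
        deficit = np.maximum(demand_cells - counts, 0)
        for cell in order:
            c = cur_flat[cell] - 1
            k = best_k[cell]
            if surplus[c] > 0 and deficit[k] > 0:
                cur_flat[cell] = k + 1
                surplus[c] -= 1
                deficit[k] -= 1
        history.append({"iteration": it, "gap": gap.copy(), "inertia": inertia.copy()})
    final = Raster(current, cell_size=lu.cell_size, nodata=lu.nodata, meta=dict(lu.meta))
    final_counts = final.class_counts()
    residual = demand_cells - final_counts
    if not converged:
        log.warning(
            "allocation stopped after %d iterations with residual %s "
            "(demand may be infeasible under the conversion constraints)",
            it,
            residual.tolist(),
        )
    return AllocationResult(
        landuse=final,
        converged=converged,
        iterations=it,
        final_counts=final_counts,
        demand_cells=demand_cells,
        residual=residual,
        history=history,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def kappa(actual: Raster, simulated: Raster) -> float:
    """Cohen's kappa agreement between two categorical rasters."""
    if not actual.same_geometry(simulated):
        raise ValueError("rasters must share geometry")
    a, b = actual.data.ravel(), simulated.data.ravel()
    valid = (a != actual.nodata) & (b != simulated.nodata)
    if np.array_equal(a[valid], b[valid]):
        return 1.0
    return float(cohen_kappa_score(a[valid], b[valid]))
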