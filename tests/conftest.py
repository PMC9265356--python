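import numpy as np
import pytest

from pleconflict import Raster, SynthConfig, gen_drivers, gen_landuse


@pytest.fixture(scope="session")
def cfg_small() -> SynthConfig:
    return SynthConfig(grid_shape=(60, 60), seed=3)


@pytest.fixture(scope="session")
def drivers_small(cfg_small):
    return gen_drivers(cfg_small)


@pytest.fixture(scope="session")
def lu_small(cfg_small, drivers_small) -> Raster:
    return gen_landuse(cfg_small, drivers_small)


def brute_force_patches(data: np.ndarray, connectivity: int):
    """Independent flood-fill patch extraction for one window.

    Returns a list of (class, area_cells, perimeter_edges) with perimeter
    counted as cell edges facing a different class or the window boundary.
    """
    rows, cols = data.shape
    seen = np.zeros(data.shape, dtype=bool)
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    patches = []
    for r0 in range(rows):
        for c0 in range(cols):
            if seen[r0, c0] or data[r0, c0] == 0:
                continue
            cls = data[r0, c0]
            stack, cells = [(r0, c0)], []
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                cells.append((r, c))
                for dr, dc in steps:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < rows and 0 <= cc < cols and not seen[rr, cc]:
                        if data[rr, cc] == cls:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
            cellset = set(cells)
            perim = 0
            for r, c in cells:
                for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
                    rr, cc = r + dr, c + dc
                    if not (0 <= rr < rows and 0 <= cc < cols):
                        perim += 1
                    elif (rr, cc) not in cellset:
                        perim += 1
            patches.append((int(cls), len(cells), perim))
    return patches
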