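import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_pnn(positions: np.ndarray) -> np.ndarray:
    """O(P^2) nearest-neighbour distances, independent of any spatial index."""
    p = np.asarray(positions, dtype=float)
    diff = p[:, None, :] - p[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


def brute_force_variogram(grid: np.ndarray, axis: str, h: int) -> tuple[float, int]:
    """All-pairs loop over cells exactly h apart along one axis."""
    rows, cols = grid.shape
    total, count = 0.0, 0
    if axis == "horizontal":
        for r in range(rows):
            for c in range(cols - h):
                total += (grid[r, c] - grid[r, c + h]) ** 2
                count += 1
    else:
        for r in range(rows - h):
            for c in range(cols):
                total += (grid[r, c] - grid[r + h, c]) ** 2
                count += 1
    return total / (2.0 * count), count
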