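"""Independent oracles used by the unit and acceptance tests.

These deliberately avoid the code paths they check: exhaustive enumeration
for 1-D k-means, dense simplex grids for the diet optimizer.
"""

import itertools

import numpy as np


def best_contiguous_partition(values: np.ndarray, k: int) -> float:
    """Minimal within-cluster SS over all contiguous 1-D partitions.

    The optimal 1-D k-means partition is contiguous in sorted order, so
    enumerating the C(n-1, k-1) cut placements is an exact oracle.
    """
    sv = np.sort(np.asarray(values, dtype=float))
    n = sv.size
    best = np.inf
    for cuts in itertools.combinations(range(1, n), k - 1):
        edges = (0, *cuts, n)
        ssw = 0.0
        for a, b in zip(edges[:-1], edges[1:]):
            seg = sv[a:b]
            ssw += float(np.sum((seg - seg.mean()) ** 2))
        best = min(best, ssw)
    return best


def simplex_grid(t: int, step: float) -> np.ndarray:
    """All simplex points with coordinates on a grid of the given step."""
    n = round(1 / step)
    if t == 2:
        a = np.arange(n + 1) / n
        return np.column_stack([a, 1 - a])
    if t == 3:
        pts = []
        for i in range(n + 1):
            j = np.arange(n - i + 1)
            pts.append(np.column_stack([np.full(j.size, i), j, n - i - j]) / n)
        return np.vstack(pts)
    raise ValueError("grids implemented for 2 and 3 taxa")


def grid_min_kl(y: np.ndarray, means: np.ndarray, step: float) -> float:
    """Minimal symmetrized KL over the simplex grid of mixtures of ``means``."""
    G = simplex_grid(means.shape[0], step)
    log_y = np.log(y)
    best = np.inf
    for block in np.array_split(G, max(1, G.shape[0] // 100_000)):
        yhat = block @ means
        kl = np.sum((y - yhat) * (log_y - np.log(yhat)), axis=1)
        best = min(best, float(kl.min()))
    return best
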