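import numpy as np
import pytest

from cctopo.grid import VoxelGrid
from cctopo.popmap import NormalizedMap, StreamlineCounts
from cctopo.synthetic import make_area_templates, make_cc_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    """Small elongated CC grid (24 x 6)."""
    return make_cc_grid(24, 6, 0.18)


@pytest.fixture
def templates(grid):
    lo, hi = grid.x_mm.min(), grid.x_mm.max()
    span = hi - lo
    specs = [("A", lo + 0.25 * span, 0.4, 2000.0),
             ("B", lo + 0.5 * span, 0.4, 2000.0),
             ("C", lo + 0.75 * span, 0.4, 2000.0)]
    return make_area_templates(grid, specs)


def flat_grid(n_voxels: int) -> VoxelGrid:
    """Fully-masked rectangular grid with exactly ``n_voxels`` voxels."""
    n_y = 2
    assert n_voxels % n_y == 0
    n_x = n_voxels // n_y
    return VoxelGrid(shape=(n_x, n_y), voxel_size=1.0, origin=(0, 0),
                     mask=np.ones((n_x, n_y), dtype=bool))


def nm_from_values(grid: VoxelGrid, values: np.ndarray, *, side="left",
                   subject="s1", age=6.0, areas=None) -> NormalizedMap:
    """Wrap a (V, A) value array as a NormalizedMap for direct map tests."""
    values = np.asarray(values, dtype=float)
    if areas is None:
        areas = tuple(f"a{j}" for j in range(values.shape[1]))
    return NormalizedMap(subject_id=subject, scan_age=age, side=side,
                         areas=tuple(areas), values=values,
                         zero_total_flags=values.sum(axis=1) == 0, grid=grid)


def counts_from_array(grid: VoxelGrid, counts: np.ndarray, *, side="left",
                      subject="s1", age=6.0, areas=None) -> StreamlineCounts:
    counts = np.asarray(counts)
    if areas is None:
        areas = tuple(f"a{j}" for j in range(counts.shape[1]))
    return StreamlineCounts(subject_id=subject, scan_age=age, side=side,
                            areas=tuple(areas), counts=counts, grid=grid)


# ----------------------------------------------------------------------- #
# independent oracles shared across test modules


def flood_fill_8(mask: np.ndarray, start) -> set:
    """BFS flood fill with 8-connectivity, independent of scipy."""
    n_x, n_y = mask.shape
    seen = {tuple(start)}
    stack = [tuple(start)]
    while stack:
        x, y = stack.pop()
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                if dx == 0 and dy == 0:
                    continue
                nx, ny = x + dx, y + dy
                if (0 <= nx < n_x and 0 <= ny < n_y and mask[nx, ny]
                        and (nx, ny) not in seen):
                    seen.add((nx, ny))
                    stack.append((nx, ny))
    return seen


def outer_boundary_oracle(mask: np.ndarray) -> set:
    """Mask voxels 4-adjacent to the outside (grid edge counts as outside).

    Voxels adjacent only to interior holes are excluded (hole suppression):
    the outside background is the 4-connected background region touching
    the grid border of a 1-voxel padded frame.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    bg = ~padded
    n_x, n_y = bg.shape
    outer = np.zeros_like(bg)
    stack = [(0, 0)]
    outer[0, 0] = True
    while stack:
        x, y = stack.pop()
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < n_x and 0 <= ny < n_y and bg[nx, ny] and not outer[nx, ny]:
                outer[nx, ny] = True
                stack.append((nx, ny))
    result = set()
    for x, y in np.argwhere(mask):
        px, py = x + 1, y + 1
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if outer[px + dx, py + dy]:
                result.add((int(x), int(y)))
                break
    return result


def bh_stepup_oracle(pvals, alpha=0.05) -> np.ndarray:
    """Literal step-up definition: reject ranks 1..k where k is the largest
    i with p_(i) <= i/m * alpha."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i / m * alpha:
            k = i
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject
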