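"""Free-energy surfaces over CV space, minimum-energy paths and barriers.

The FES is a weighted histogram estimate F(cell) = -(1/β) log p(cell),
shifted so its minimum is zero; cells never visited are flagged (infinite
free energy) rather than set to zero, and are impassable to path searches.
The barrier between two basins is defined through the minimax path: the
8-connected cell path minimizing the maximum free energy crossed, with the
barrier measured from the free energy of the starting basin cell.
Uncertainties come from block averaging over contiguous trajectory blocks.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConnectivityError, InputError

__all__ = [
    "GridSpec",
    "FESGrid",
    "PathResult",
    "estimate_fes",
    "minimum_energy_path",
    "minimax_barrier_bruteforce",
    "barrier_errors",
    "edge_barriers",
    "edge_barrier_errors",
    "EDGE_DEFINITIONS",
]


@dataclass(frozen=True)
class GridSpec:
    """Histogram grid over (CV1, CV2); defaults cover the wall-bounded range."""

    cv1_range: tuple = (-7.5, 7.5)
    cv2_range: tuple = (-7.5, 7.5)
    bins: int = 60


@dataclass
class FESGrid:
    """Gridded free energy (kcal/mol), min-shifted to 0; unvisited cells inf."""

    cv1_edges: np.ndarray
    cv2_edges: np.ndarray
    free_energy: np.ndarray  # (bins1, bins2), inf where unestimated
    occupancy: np.ndarray
    beta: float
    error: np.ndarray | None = None

    @property
    def estimated(self) -> np.ndarray:
        return np.isfinite(self.free_energy)

    def cell_of(self, point) -> tuple[int, int]:
        p = np.asarray(point, dtype=float)
        i = int(np.clip(np.searchsorted(self.cv1_edges, p[0]) - 1, 0, len(self.cv1_edges) - 2))
        j = int(np.clip(np.searchsorted(self.cv2_edges, p[1]) - 1, 0, len(self.cv2_edges) - 2))
        return i, j

    def basin_cell(self, point, radius: float = 1.5) -> tuple[int, int]:
        """Estimated cell of lowest free energy within ``radius`` of a point."""
        c1 = 0.5 * (self.cv1_edges[:-1] + self.cv1_edges[1:])
        c2 = 0.5 * (self.cv2_edges[:-1] + self.cv2_edges[1:])
        X, Y = np.meshgrid(c1, c2, indexing="ij")
        p = np.asarray(point, dtype=float)
        near = (X - p[0]) ** 2 + (Y - p[1]) ** 2 <= radius**2
        masked = np.where(near & self.estimated, self.free_energy, np.inf)
        if not np.isfinite(masked).any():
            raise InputError(f"no estimated cells within {radius} of {point}")
        return tuple(int(v) for v in np.unravel_index(np.argmin(masked), masked.shape))

    def write_text(self, path) -> None:
        """Three-column text grid (cv1, cv2, free_energy); inf for unvisited."""
        c1 = 0.5 * (self.cv1_edges[:-1] + self.cv1_edges[1:])
        c2 = 0.5 * (self.cv2_edges[:-1] + self.cv2_edges[1:])
        with open(path, "w") as fh:
            fh.write("# cv1 cv2 free_energy\n")
            for i, a in enumerate(c1):
                for j, b in enumerate(c2):
                    fh.write(f"{a:.6f} {b:.6f} {self.free_energy[i, j]:.6f}\n")


def estimate_fes(
    cv_samples, weights, grid_spec: GridSpec, beta: float, smooth_sigma: float = 0.0
) -> FESGrid:
    """Weighted histogram free energy over the grid, min-shifted to zero.

    ``smooth_sigma`` (CV units) optionally convolves the weighted occupancy
    with a Gaussian of that fixed physical width before taking the log.
    Smoothing at the scale of the narrowest physical feature suppresses
    single-cell sampling spikes without touching broader structure; cells
    far from any sample stay flagged as unestimated.
    """
    s = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    w = np.asarray(weights, dtype=float)
    if len(w) != len(s):
        raise InputError("weights do not align with samples")
    edges1 = np.linspace(*grid_spec.cv1_range, grid_spec.bins + 1)
    edges2 = np.linspace(*grid_spec.cv2_range, grid_spec.bins + 1)
    H, _, _ = np.histogram2d(s[:, 0], s[:, 1], bins=[edges1, edges2], weights=w)
    if H.sum() == 0:
        raise InputError("all samples fall outside the grid")
    if smooth_sigma > 0:
        cell = (edges1[1] - edges1[0], edges2[1] - edges2[0])
        Hs = gaussian_filter(H, (smooth_sigma / cell[0], smooth_sigma / cell[1]), mode="constant")
        vis = (
            gaussian_filter((H > 0).astype(float), (smooth_sigma / cell[0], smooth_sigma / cell[1]), mode="constant")
            > 1e-3
        ) & (Hs > 0)
    else:
        Hs, vis = H, H > 0
    F = np.full_like(Hs, np.inf)
    F[vis] = -np.log(Hs[vis]) / beta
    F -= F[vis].min()
    return FESGrid(cv1_edges=edges1, cv2_edges=edges2, free_energy=F, occupancy=H, beta=beta)


@dataclass
class PathResult:
    """Minimax path between two basins and the barrier it crosses."""

    cells: list = field(default_factory=list)
    barrier: float = 0.0
    barrier_error: float | None = None
    pathway: int | None = None
    start_cell: tuple = ()
    end_cell: tuple = ()


_NEIGHBORS = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]


def minimum_energy_path(
    fes: FESGrid, start_cell: tuple[int, int], end_cell: tuple[int, int]
) -> PathResult:
    """8-connected path minimizing the maximum free energy along it.

    Dijkstra-type search with the path cost max(F) instead of a sum;
    unestimated cells are impassable.
    """
    F = fes.free_energy
    for name, cell in (("start", start_cell), ("end", end_cell)):
        if not np.isfinite(F[cell]):
            raise InputError(f"{name} cell {cell} is not estimated")
    shape = F.shape
    best = np.full(shape, np.inf)
    best[start_cell] = F[start_cell]
    prev: dict[tuple, tuple] = {}
    heap = [(best[start_cell], start_cell)]
    visited = np.zeros(shape, dtype=bool)
    while heap:
        cost, cell = heapq.heappop(heap)
        if visited[cell]:
            continue
        visited[cell] = True
        if cell == tuple(end_cell):
            break
        i, j = cell
        for di, dj in _NEIGHBORS:
            ni, nj = i + di, j + dj
            if not (0 <= ni < shape[0] and 0 <= nj < shape[1]):
                continue
            if visited[ni, nj] or not np.isfinite(F[ni, nj]):
                continue
            cand = max(cost, F[ni, nj])
            if cand < best[ni, nj]:
                best[ni, nj] = cand
                prev[(ni, nj)] = cell
                heapq.heappush(heap, (cand, (ni, nj)))
    end_cell = tuple(end_cell)
    if not visited[end_cell]:
        raise ConnectivityError(
            f"cells {tuple(start_cell)} and {end_cell} are not connected through estimated cells"
        )
    cells = [end_cell]
    while cells[-1] != tuple(start_cell):
        cells.append(prev[cells[-1]])
    cells.reverse()
    barrier = float(best[end_cell] - F[tuple(start_cell)])
    return PathResult(
        cells=cells,
        barrier=max(barrier, 0.0),
        start_cell=tuple(start_cell),
        end_cell=end_cell,
    )


def minimax_barrier_bruteforce(
    fes: FESGrid, start_cell: tuple[int, int], end_cell: tuple[int, int]
) -> float:
    """Independent oracle: smallest threshold T such that the endpoints are
    connected through estimated cells with F <= T (checked by flood fill).

    Equivalent to exhaustive enumeration over all simple paths, but feasible
    on any grid size; the returned value is the minimax path height, from
    which the barrier is height - F(start).
    """
    F = fes.free_energy
    levels = np.unique(F[np.isfinite(F)])
    lo, hi = 0, len(levels) - 1

    def connected(T: float) -> bool:
        ok = np.isfinite(F) & (F <= T)
        if not (ok[tuple(start_cell)] and ok[tuple(end_cell)]):
            return False
        stack = [tuple(start_cell)]
        seen = {tuple(start_cell)}
        while stack:
            i, j = stack.pop()
            if (i, j) == tuple(end_cell):
                return True
            for di, dj in _NEIGHBORS:
                ni, nj = i + di, j + dj
                if 0 <= ni < F.shape[0] and 0 <= nj < F.shape[1]:
                    if ok[ni, nj] and (ni, nj) not in seen:
                        seen.add((ni, nj))
                        stack.append((ni, nj))
        return False

    if not connected(levels[hi]):
        raise ConnectivityError("endpoints are not connected at any level")
    while lo < hi:
        mid = (lo + hi) // 2
        if connected(levels[mid]):
            hi = mid
        else:
            lo = mid + 1
    return float(levels[lo] - F[tuple(start_cell)])


# (edge name, start state, end state, corridor side, reference state)
# side +1 restricts the path to cv1-cv2 >= -tol (the INT1 corridor), -1 to
# the INT2 corridor; the reference state fixes which basin the printed
# barrier is measured from (the overall INT1->POST barrier is quoted from
# PRE, the INT2->POST one from INT2 itself).
EDGE_DEFINITIONS = [
    ("PRE-INT1", "PRE", "INT1", +1, "PRE"),
    ("INT1-POST", "INT1", "POST", +1, "PRE"),
    ("PRE-INT2", "PRE", "INT2", -1, "PRE"),
    ("INT2-POST", "INT2", "POST", -1, "INT2"),
]


def _corridor_mask(grid: FESGrid, side: int, tol: float) -> np.ndarray:
    c1 = 0.5 * (grid.cv1_edges[:-1] + grid.cv1_edges[1:])
    c2 = 0.5 * (grid.cv2_edges[:-1] + grid.cv2_edges[1:])
    X, Y = np.meshgrid(c1, c2, indexing="ij")
    return side * (X - Y) >= -tol


def edge_barriers(
    grid: FESGrid,
    state_centers: dict,
    basin_radius: float = 1.5,
    corridor_tol: float = 1.0,
) -> dict:
    """Barriers of the four state-connecting edges from a (CV1, CV2) FES.

    The two stepwise paths live in opposite half-planes of the anti-diagonal
    coordinate cv1 - cv2, so each edge's minimax path is searched within its
    own corridor (otherwise the path between non-adjacent basins would
    detour through the other intermediate and report the wrong saddle).
    Returns {edge: barrier} on the conventions of ``EDGE_DEFINITIONS``.
    """
    out = {}
    for name, a, b, side, ref in EDGE_DEFINITIONS:
        mask = _corridor_mask(grid, side, corridor_tol)
        Fm = np.where(mask, grid.free_energy, np.inf)
        gm = FESGrid(grid.cv1_edges, grid.cv2_edges, Fm, grid.occupancy, grid.beta)
        ca = gm.basin_cell(state_centers[a], basin_radius)
        cb = gm.basin_cell(state_centers[b], basin_radius)
        peak = minimum_energy_path(gm, ca, cb).barrier + Fm[ca]
        cref = gm.basin_cell(state_centers[ref], basin_radius)
        out[name] = float(peak - Fm[cref])
    return out


def edge_barrier_errors(
    cv_samples,
    weights,
    grid_spec: GridSpec,
    beta: float,
    state_centers: dict,
    n_blocks: int = 4,
    smooth_sigma: float = 0.0,
    basin_radius: float = 1.5,
    corridor_tol: float = 1.0,
) -> tuple[dict, int]:
    """Block-average standard errors of the four edge barriers.

    Contiguous trajectory blocks are re-estimated independently; blocks in
    which an edge's endpoints are unestimated or disconnected are skipped
    for that edge (the skip count is returned alongside).
    """
    if n_blocks < 2:
        raise InputError("n_blocks must be >= 2")
    s = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    w = np.asarray(weights, dtype=float)
    bounds = np.linspace(0, len(s), n_blocks + 1).astype(int)
    per_edge: dict[str, list] = {name: [] for name, *_ in EDGE_DEFINITIONS}
    skipped = 0
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        wb = w[sl]
        if wb.sum() == 0:
            skipped += len(per_edge)
            continue
        g = estimate_fes(s[sl], wb / wb.sum(), grid_spec, beta, smooth_sigma)
        for name, a, bb, side, ref in EDGE_DEFINITIONS:
            try:
                mask = _corridor_mask(g, side, corridor_tol)
                Fm = np.where(mask, g.free_energy, np.inf)
                gm = FESGrid(g.cv1_edges, g.cv2_edges, Fm, g.occupancy, g.beta)
                ca = gm.basin_cell(state_centers[a], basin_radius)
                cb = gm.basin_cell(state_centers[bb], basin_radius)
                peak = minimum_energy_path(gm, ca, cb).barrier + Fm[ca]
                cref = gm.basin_cell(state_centers[ref], basin_radius)
                per_edge[name].append(float(peak - Fm[cref]))
            except (InputError, ConnectivityError):
                skipped += 1
    errs = {}
    for name, vals in per_edge.items():
        arr = np.asarray(vals)
        errs[name] = float(arr.std(ddof=0) / np.sqrt(len(arr))) if len(arr) >= 2 else float("nan")
    return errs, skipped


def barrier_errors(
    cv_samples,
    weights,
    grid_spec: GridSpec,
    beta: float,
    endpoint_points: list[tuple],
    n_blocks: int = 4,
    basin_radius: float = 1.5,
) -> tuple[np.ndarray, int]:
    """Block-average barrier uncertainties.

    Splits the frames into ``n_blocks`` contiguous blocks, recomputes each
    requested barrier (pairs of CV-space points) per block, and reports the
    standard error SD/sqrt(n_blocks) per barrier.  Blocks in which an
    endpoint basin is unestimated or disconnected are skipped; the count of
    skipped (block, barrier) evaluations is returned alongside.
    """
    if n_blocks < 2:
        raise InputError("n_blocks must be >= 2")
    s = np.atleast_2d(np.asarray(cv_samples, dtype=float))
    w = np.asarray(weights, dtype=float)
    bounds = np.linspace(0, len(s), n_blocks + 1).astype(int)
    per_block = []
    skipped = 0
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        wb = w[sl]
        if wb.sum() == 0:
            skipped += len(endpoint_points)
            continue
        fes_b = estimate_fes(s[sl], wb / wb.sum(), grid_spec, beta)
        row = []
        for p_start, p_end in endpoint_points:
            try:
                c0 = fes_b.basin_cell(p_start, basin_radius)
                c1 = fes_b.basin_cell(p_end, basin_radius)
                row.append(minimum_energy_path(fes_b, c0, c1).barrier)
            except (InputError, ConnectivityError):
                row.append(np.nan)
                skipped += 1
        per_block.append(row)
    arr = np.asarray(per_block, dtype=float)
    errs = np.empty(len(endpoint_points))
    for k in range(len(endpoint_points)):
        col = arr[:, k] if len(arr) else np.array([])
        col = col[np.isfinite(col)]
        errs[k] = col.std(ddof=0) / np.sqrt(len(col)) if len(col) >= 2 else np.nan
    return errs, skipped
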