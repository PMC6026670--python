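"""Wet-areas mapping: from a DEM to the cartographic depth-to-water index.

The depth-to-water (DTW, meters) index approximates depth to the water
table at each cell as the least cumulative-slope path cost from the cell
to the nearest hydrological source cell:

    DTW = [ sum_i (dz_i / dx_i) * a_i ] * x_c

where the sum runs over steps i of an 8-connected path, dz/dx is the slope
of the step (dx = x_c for cardinal steps, sqrt(2) * x_c for diagonal ones),
a_i is a path-direction factor, and x_c is the cell size. Sources are the
cells whose D8 upslope contributing area reaches the flow-initiation
threshold lambda (hectares); sources have DTW = 0 by definition. Lower
lambda predicts a wetter landscape (more sources), higher lambda a drier
one.

The stages are: depression filling (priority-flood with an epsilon
gradient, so the surface drains everywhere), D8 steepest-descent flow
directions, flow accumulation in topological order, source extraction at
lambda, and a multi-source Dijkstra computing the exact least-cost DTW.
"""
from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .raster import DEMGrid

logger = logging.getLogger(__name__)

__all__ = [
    "FlowField", "AccumulationGrid", "SourceMask", "DTWParams", "DTWGrid",
    "DTWSuiteResult", "fill_depressions", "d8_flow_directions",
    "flow_accumulation", "extract_sources", "compute_dtw", "dtw_suite",
    "sample_dtw_at_points", "DIRECTION_NAMES", "DIRECTION_OFFSETS",
    "OUTLET", "NODATA",
]

# D8 directions in fixed clockwise tie-break order starting East.
DIRECTION_NAMES = ("E", "NE", "N", "NW", "W", "SW", "S", "SE")
DIRECTION_OFFSETS = np.array(
    [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)],
    dtype=int,
)
# Step length in cell units: 1 cardinal, sqrt(2) diagonal.
_STEP_LENGTH = np.array([1.0, np.sqrt(2), 1.0, np.sqrt(2)] * 2)
_IS_DIAGONAL = np.array([False, True] * 4)

OUTLET = -1   # drains off-grid (boundary or next to nodata)
NODATA = -2


@dataclass
class FlowField:
    """Per-cell D8 flow direction codes aligned to a DEM.

    ``direction`` holds an index into :data:`DIRECTION_OFFSETS`, or
    :data:`OUTLET` / :data:`NODATA`.
    """

    direction: np.ndarray
    cell_size: float

    @property
    def shape(self):
        return self.direction.shape

    def receiver_flat_index(self) -> np.ndarray:
        """Flat index of each cell's receiver; -1 for outlets/nodata."""
        n_rows, n_cols = self.direction.shape
        rows, cols = np.indices(self.direction.shape)
        d = self.direction
        recv = np.full(self.direction.shape, -1, dtype=np.int64)
        flows = d >= 0
        dr = DIRECTION_OFFSETS[d[flows], 0]
        dc = DIRECTION_OFFSETS[d[flows], 1]
        recv[flows] = (rows[flows] + dr) * n_cols + (cols[flows] + dc)
        return recv.ravel()


@dataclass
class AccumulationGrid:
    """Upslope contributing area per cell, in hectares (includes the cell)."""

    upslope_area: np.ndarray
    cell_size: float


@dataclass
class SourceMask:
    """Cells flagged as hydrological sources at one flow-initiation threshold."""

    is_source: np.ndarray
    lambda_ha: float


@dataclass
class DTWParams:
    """Tunables of the DTW path cost.

    diagonal_factor is the path factor ``a`` for diagonal steps (cardinal
    steps always use a = 1). The default sqrt(2) makes a diagonal step
    contribute exactly its elevation rise, so DTW keeps its meters
    reading; 2.0 is also accepted. step_cost_mode 'rise_only' charges
    max(dz, 0) per step walking away from the source; 'absolute' charges
    |dz|.
    """

    lambda_ha: float = 4.0
    diagonal_factor: float = np.sqrt(2)
    step_cost_mode: str = "rise_only"
    connectivity: int = 8

    def __post_init__(self):
        if not self.lambda_ha > 0:
            raise ValueError("lambda_ha must be positive")
        if not self.diagonal_factor > 0:
            raise ValueError("diagonal_factor must be positive")
        if self.step_cost_mode not in ("rise_only", "absolute"):
            raise ValueError("step_cost_mode must be 'rise_only' or 'absolute'")
        if self.connectivity != 8:
            raise ValueError("only 8-neighbor connectivity is supported")


@dataclass
class DTWGrid:
    """Depth-to-water (meters) per cell for one flow-initiation threshold."""

    dtw: np.ndarray
    lambda_ha: float
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)


@dataclass
class DTWSuiteResult:
    """DTW rasters across several thresholds from one hydrology pass."""

    dtw_by_lambda: dict
    correlation: "object"          # pandas DataFrame, lambda x lambda
    skipped: list = field(default_factory=list)
    filled_dem: DEMGrid | None = None
    flow: FlowField | None = None
    accumulation: AccumulationGrid | None = None


def _neighbors(shape):
    """Yield (direction, dr, dc) triples in tie-break order."""
    for d, (dr, dc) in enumerate(DIRECTION_OFFSETS):
        yield d, dr, dc


def fill_depressions(dem: DEMGrid, epsilon: float | None = None) -> DEMGrid:
    """Priority-flood depression filling with an epsilon drainage gradient.

    Returns a grid whose every non-nodata cell has a strictly descending
    8-neighbor path to the grid boundary (or to a nodata-adjacent cell)
    when ``epsilon > 0``. Cells outside depressions and flats are left
    unchanged. Default epsilon is ``1e-6 * cell_size``.
    """
    if epsilon is None:
        epsilon = 1e-6 * dem.cell_size
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    z = dem.elevations
    mask = dem.nodata_mask
    n_rows, n_cols = z.shape
    if mask.all():
        raise ValueError("all-nodata grid cannot be filled")

    out = z.copy()
    closed = mask.copy()
    heap: list[tuple[float, int, int, int]] = []
    counter = 0
    # Seed: boundary cells and cells adjacent to nodata (both drain off).
    pad = np.pad(mask, 1, constant_values=True)
    adjacent_nodata = np.zeros_like(mask)
    for _, dr, dc in _neighbors(z.shape):
        adjacent_nodata |= pad[1 + dr:1 + dr + n_rows, 1 + dc:1 + dc + n_cols]
    seeds = (~mask) & adjacent_nodata
    for r, c in zip(*np.nonzero(seeds)):
        heapq.heappush(heap, (out[r, c], counter, r, c))
        counter += 1
        closed[r, c] = True
    while heap:
        zc, _, r, c = heapq.heappop(heap)
        for _, dr, dc in _neighbors(z.shape):
            nr, nc = r + dr, c + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols and not closed[nr, nc]:
                closed[nr, nc] = True
                out[nr, nc] = max(z[nr, nc], zc + epsilon)
                heapq.heappush(heap, (out[nr, nc], counter, nr, nc))
                counter += 1
    return dem.with_elevations(out)


def d8_flow_directions(dem: DEMGrid) -> FlowField:
    """Steepest-descent D8 flow directions on a depression-filled DEM.

    Each cell drains to the 8-neighbor with the steepest positive drop per
    unit distance (x_c cardinal, sqrt(2) x_c diagonal); ties are broken in
    the fixed clockwise order E, NE, N, NW, W, SW, S, SE. Cells with no
    lower neighbor become OUTLET when they touch the boundary or nodata;
    an interior cell with no lower neighbor means the DEM was not filled.
    """
    z = dem.elevations
    mask = dem.nodata_mask
    n_rows, n_cols = z.shape
    zp = np.pad(z, 1, constant_values=np.nan)
    grads = np.full((8, n_rows, n_cols), -np.inf)
    for d, dr, dc in _neighbors(z.shape):
        nz = zp[1 + dr:1 + dr + n_rows, 1 + dc:1 + dc + n_cols]
        g = (z - nz) / (_STEP_LENGTH[d] * dem.cell_size)
        grads[d] = np.where(np.isfinite(g), g, -np.inf)
    best = np.argmax(grads, axis=0)            # first max wins the tie
    best_grad = np.take_along_axis(grads, best[None], axis=0)[0]

    direction = best.astype(np.int8)
    no_drop = best_grad <= 0
    pad_mask = np.pad(mask, 1, constant_values=True)
    touches_edge = np.zeros_like(mask)
    for _, dr, dc in _neighbors(z.shape):
        touches_edge |= pad_mask[1 + dr:1 + dr + n_rows, 1 + dc:1 + dc + n_cols]
    direction[no_drop & touches_edge] = OUTLET
    direction[mask] = NODATA
    interior_pits = no_drop & ~touches_edge & ~mask
    if interior_pits.any():
        r, c = np.argwhere(interior_pits)[0]
        raise ValueError(
            f"interior cell ({r}, {c}) has no lower neighbor; the DEM has "
            "unresolved pits or flats - run fill_depressions first")
    return FlowField(direction, dem.cell_size)


def flow_accumulation(flow: FlowField, cell_size: float | None = None
                      ) -> AccumulationGrid:
    """Upslope contributing area (hectares) by topological accumulation.

    area(v) = cell area + sum of donors' areas; the outlet cells jointly
    account for the whole non-nodata grid area.
    """
    if cell_size is None:
        cell_size = flow.cell_size
    d = flow.direction
    n = d.size
    recv = flow.receiver_flat_index()
    valid = (d.ravel() != NODATA)
    cell_ha = cell_size ** 2 / 1e4
    area = np.where(valid, cell_ha, 0.0)

    indeg = np.bincount(recv[recv >= 0], minlength=n)
    stack = list(np.nonzero(valid & (indeg == 0))[0])
    n_done = 0
    while stack:
        u = stack.pop()
        n_done += 1
        v = recv[u]
        if v >= 0:
            area[v] += area[u]
            indeg[v] -= 1
            if indeg[v] == 0:
                stack.append(v)
    if n_done != int(valid.sum()):
        raise ValueError("flow field contains a cycle; cannot accumulate")
    out = area.reshape(d.shape)
    out[~valid.reshape(d.shape)] = np.nan
    return AccumulationGrid(out, cell_size)


def extract_sources(acc: AccumulationGrid, lambda_ha: float) -> SourceMask:
    """Flag cells whose accumulation reaches the flow-initiation threshold."""
    if not lambda_ha > 0:
        raise ValueError("lambda_ha must be positive")
    with np.errstate(invalid="ignore"):
        is_source = np.nan_to_num(acc.upslope_area, nan=-np.inf) >= lambda_ha
    if not is_source.any():
        raise ValueError(
            f"no hydrological sources at this threshold (lambda = {lambda_ha} ha)")
    return SourceMask(is_source, float(lambda_ha))


def compute_dtw(dem: DEMGrid, sources: SourceMask,
                params: DTWParams | None = None) -> DTWGrid:
    """Exact least-cost DTW by multi-source Dijkstra over the 8-neighbor grid.

    The step cost from cell u to neighbor v is
    ``cost(z_v - z_u) / dx * a * x_c`` with dx = x_c (cardinal) or
    sqrt(2) x_c (diagonal), a = 1 (cardinal) or ``params.diagonal_factor``
    (diagonal), and cost() = max(., 0) in 'rise_only' mode or abs() in
    'absolute' mode. All weights are >= 0, so Dijkstra is exact. Source
    cells get DTW = 0; paths never traverse nodata; cells unreachable from
    any source (walled off by nodata) come back NaN.
    """
    if params is None:
        params = DTWParams(lambda_ha=sources.lambda_ha)
    if sources.is_source.shape != dem.shape:
        raise ValueError("sources and DEM are misaligned")
    if not sources.is_source.any():
        raise ValueError("empty source mask")
    z = dem.elevations
    mask = dem.nodata_mask
    n_rows, n_cols = z.shape
    # a/dx * x_c prefactor per direction
    factor = np.where(
        _IS_DIAGONAL,
        params.diagonal_factor / (np.sqrt(2) * dem.cell_size) * dem.cell_size,
        1.0,
    )
    rise_only = params.step_cost_mode == "rise_only"

    dist = np.full(z.shape, np.inf)
    seed = sources.is_source & ~mask
    dist[seed] = 0.0
    heap = [(0.0, int(r) * n_cols + int(c)) for r, c in zip(*np.nonzero(seed))]
    heapq.heapify(heap)
    offsets = [(d, int(dr), int(dc)) for d, (dr, dc) in enumerate(DIRECTION_OFFSETS)]
    flat = dist.ravel()
    zf = z.ravel()
    maskf = mask.ravel()
    while heap:
        du, u = heapq.heappop(heap)
        if du > flat[u]:
            continue
        ur, uc = divmod(u, n_cols)
        zu = zf[u]
        for d, dr, dc in offsets:
            nr, nc = ur + dr, uc + dc
            if 0 <= nr < n_rows and 0 <= nc < n_cols:
                v = nr * n_cols + nc
                if maskf[v]:
                    continue
                dz = zf[v] - zu
                w = (max(dz, 0.0) if rise_only else abs(dz)) * factor[d]
                alt = du + w
                if alt < flat[v]:
                    flat[v] = alt
                    heapq.heappush(heap, (alt, v))
    dtw = dist.copy()
    unreachable = np.isinf(dtw) & ~mask
    if unreachable.any():
        logger.warning("%d cells unreachable from any source (nodata barriers)",
                       int(unreachable.sum()))
    dtw[np.isinf(dtw)] = np.nan
    dtw[mask] = np.nan
    return DTWGrid(dtw, sources.lambda_ha, dem.cell_size, dem.origin)


DEFAULT_THRESHOLDS_HA = (0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 16.0)


def dtw_suite(dem: DEMGrid, thresholds=DEFAULT_THRESHOLDS_HA,
              params: DTWParams | None = None) -> DTWSuiteResult:
    """DTW rasters for a list of flow-initiation thresholds.

    Runs filling, D8 and accumulation once, then extracts sources and
    computes DTW per threshold. A threshold with no sources is skipped with
    a log message (it is an error only if every threshold fails). Also
    returns the pairwise Pearson correlation matrix of per-cell DTW values
    across thresholds, which quantifies how functionally equivalent the
    thresholds are on the given terrain.
    """
    import pandas as pd

    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(t <= 0 for t in thresholds):
        raise ValueError("all thresholds must be positive")
    if params is None:
        params = DTWParams()
    filled = fill_depressions(dem)
    flow = d8_flow_directions(filled)
    acc = flow_accumulation(flow)
    dtw_by_lambda = {}
    skipped = []
    for lam in thresholds:
        try:
            src = extract_sources(acc, lam)
        except ValueError as exc:
            logger.warning("threshold %s ha skipped: %s", lam, exc)
            skipped.append(float(lam))
            continue
        p = DTWParams(lambda_ha=lam, diagonal_factor=params.diagonal_factor,
                      step_cost_mode=params.step_cost_mode)
        dtw_by_lambda[float(lam)] = compute_dtw(filled, src, p)
    if not dtw_by_lambda:
        raise ValueError("no threshold produced any hydrological source")

    lams = sorted(dtw_by_lambda)
    stack = np.column_stack([dtw_by_lambda[l].dtw.ravel() for l in lams])
    ok = np.all(np.isfinite(stack), axis=1)
    if ok.sum() >= 2:
        corr = np.corrcoef(stack[ok].T)
    else:
        corr = np.full((len(lams), len(lams)), np.nan)
    corr_df = pd.DataFrame(corr, index=lams, columns=lams)
    return DTWSuiteResult(dtw_by_lambda, corr_df, skipped, filled, flow, acc)


def sample_dtw_at_points(dtw: DTWGrid, points) -> np.ndarray:
    """DTW values at points in map coordinates (nearest-cell rule).

    Each point takes the value of the cell containing it (no
    interpolation). Points outside the grid extent or on nodata cells
    raise a ValueError listing the offenders.
    """
    n_rows, n_cols = dtw.dtw.shape
    x0, y0 = dtw.origin
    out = np.empty(len(points))
    bad = []
    for i, (x, y) in enumerate(points):
        col = int(np.floor((x - x0) / dtw.cell_size))
        row = int(np.floor((y0 - y) / dtw.cell_size))
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            bad.append((i, (x, y), "outside extent"))
            continue
        v = dtw.dtw[row, col]
        if not np.isfinite(v):
            bad.append((i, (x, y), "nodata cell"))
            continue
        out[i] = v
    if bad:
        detail = "; ".join(f"point {i} {xy}: {why}" for i, xy, why in bad)
        raise ValueError(f"cannot sample DTW: {detail}")
    return out
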