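"""Per-stream-cell pour-point watersheds and inverse-distance weights.

Every stream grid cell acts as a pour point (outlet): its sub-catchment is
the set of cells whose D8 flow path passes through it.  Two distance fields
are attached to each sub-catchment:

* straight-line ("as the crow flies") distance from every catchment cell to
  the outlet, in cell units;
* along-network ("as the fish swims") distance, defined on the catchment's
  stream cells only, counted in flow steps down the drainage path.

Both feed the inverse-distance weighting w = 1/d used by the weighted
upstream metrics, so conditions at and just upstream of a cell dominate its
value and far-upstream conditions are progressively discounted.  The
weighting is undefined at distance zero, so the outlet itself is assigned
d = 1: its weight is the maximum possible, 1, and weights are bounded in
(0, 1].

Along-network steps count 1 per flow step by default (topological path
length); pass ``diagonal_sqrt2=True`` to weight diagonal steps by sqrt(2).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .errors import InvalidOutletError, InvalidParameterError, FlowError
from .grid import D8_DISTANCES, FlowDirectionGrid

__all__ = [
    "SubCatchment",
    "delineate",
    "euclidean_distance",
    "network_distance",
    "idw_weights",
    "delineate_all",
    "iter_subcatchments",
]


@dataclass
class SubCatchment:
    """Upstream contributing area of one stream cell.

    ``cells`` is an (n, 2) array of (row, col) indices including the outlet
    (always first).  ``d_euclid`` aligns with ``cells``; ``d_network`` too,
    but holds NaN on cells off the stream network.  ``is_stream`` marks
    which member cells are stream cells.
    """

    outlet: tuple[int, int]
    cells: np.ndarray
    d_euclid: np.ndarray
    d_network: np.ndarray
    is_stream: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def w_euclid(self) -> np.ndarray:
        return idw_weights(self.d_euclid)

    @property
    def w_network(self) -> np.ndarray:
        """Weights over stream cells (NaN elsewhere, matching d_network)."""
        w = np.full_like(self.d_network, np.nan)
        ok = ~np.isnan(self.d_network)
        w[ok] = idw_weights(self.d_network[ok])
        return w

    def cell_set(self) -> set[tuple[int, int]]:
        return {tuple(rc) for rc in self.cells}


def _donor_adjacency(fd: FlowDirectionGrid) -> tuple[np.ndarray, np.ndarray]:
    """CSR-style donor lists: donors of cell i are donors[start[i]:start[i+1]]."""
    down = fd.downstream_index()
    n = down.size
    has = down >= 0
    counts = np.bincount(down[has], minlength=n)
    start = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    donors = np.empty(has.sum(), dtype=np.int64)
    fill = start[:-1].copy()
    for src in np.nonzero(has)[0]:
        t = down[src]
        donors[fill[t]] = src
        fill[t] += 1
    return start, donors


def delineate(fd: FlowDirectionGrid, outlet: tuple[int, int]) -> set[tuple[int, int]]:
    """All cells whose flow path reaches ``outlet`` (outlet included)."""
    r, c = outlet
    nrows, ncols = fd.shape
    if not (0 <= r < nrows and 0 <= c < ncols) or not fd.valid[r, c]:
        raise InvalidOutletError(f"outlet {outlet} is outside the data area")
    start, donors = _donor_adjacency(fd)
    return {
        (int(i // ncols), int(i % ncols))
        for i in _upstream_cells(start, donors, r * ncols + c)
    }


def _upstream_cells(start: np.ndarray, donors: np.ndarray, outlet_flat: int) -> list[int]:
    """BFS over the donor graph from the outlet; returns flat indices,
    outlet first, in deterministic (breadth-first, row-major-donor) order."""
    seen = [outlet_flat]
    queue = deque([outlet_flat])
    while queue:
        i = queue.popleft()
        for j in sorted(donors[start[i]: start[i + 1]].tolist()):
            seen.append(j)
            queue.append(j)
    return seen


def euclidean_distance(
    cells: np.ndarray, outlet: tuple[int, int]
) -> np.ndarray:
    """Straight-line distance (cell units) from each cell to the outlet.

    The outlet's own distance is set to 1 by the weighting convention.
    """
    cells = np.asarray(cells)
    d = np.hypot(cells[:, 0] - outlet[0], cells[:, 1] - outlet[1]).astype(float)
    d[(cells[:, 0] == outlet[0]) & (cells[:, 1] == outlet[1])] = 1.0
    return d


def network_distance(
    cells: np.ndarray,
    fd: FlowDirectionGrid,
    streams: np.ndarray,
    outlet: tuple[int, int],
    diagonal_sqrt2: bool = False,
) -> np.ndarray:
    """Along-flow-path distance to the outlet, on stream cells only.

    Aligned with ``cells``; NaN where the member cell is not a stream cell.
    Distance is the number of flow steps (optionally sqrt(2) per diagonal
    step); the outlet gets 1.
    """
    cells = np.asarray(cells)
    nrows, ncols = fd.shape
    streams = np.asarray(streams, dtype=bool)
    down = fd.downstream_index()
    codes = fd.codes.ravel()

    member = {(int(r), int(c)): i for i, (r, c) in enumerate(cells)}
    out = np.full(len(cells), np.nan)
    # walk downstream from each stream member, accumulating step lengths;
    # memoise distances at stream cells already resolved
    resolved: dict[int, float] = {outlet[0] * ncols + outlet[1]: 0.0}
    outlet_flat = outlet[0] * ncols + outlet[1]

    for i, (r, c) in enumerate(cells):
        if not streams[r, c]:
            continue
        flat = int(r) * ncols + int(c)
        path = []
        cur = flat
        dist = None
        while True:
            if cur in resolved:
                dist = resolved[cur]
                break
            path.append(cur)
            code = codes[cur]
            if code < 0 or down[cur] < 0:
                raise FlowError(
                    f"stream cell {(cur // ncols, cur % ncols)} has no path to "
                    f"outlet {outlet}"
                )
            cur = down[cur]
        # unwind, adding step lengths back up the path
        for node in reversed(path):
            step = D8_DISTANCES[codes[node]] if diagonal_sqrt2 else 1.0
            dist = dist + step
            resolved[node] = dist
        out[i] = max(1.0, resolved[flat])
    return out


def idw_weights(d: np.ndarray) -> np.ndarray:
    """Inverse-distance weights w = 1/d; requires every d >= 1."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 1.0):
        raise InvalidParameterError("distances must be >= 1 for 1/d weighting")
    return 1.0 / d


def _build_subcatchment(
    fd: FlowDirectionGrid,
    streams: np.ndarray,
    start: np.ndarray,
    donors: np.ndarray,
    outlet: tuple[int, int],
    diagonal_sqrt2: bool,
) -> SubCatchment:
    nrows, ncols = fd.shape
    flat = _upstream_cells(start, donors, outlet[0] * ncols + outlet[1])
    cells = np.column_stack((np.asarray(flat) // ncols, np.asarray(flat) % ncols))
    is_stream = streams[cells[:, 0], cells[:, 1]]
    return SubCatchment(
        outlet=outlet,
        cells=cells,
        d_euclid=euclidean_distance(cells, outlet),
        d_network=network_distance(cells, fd, streams, outlet, diagonal_sqrt2),
        is_stream=is_stream,
    )


def iter_subcatchments(
    fd: FlowDirectionGrid,
    streams: np.ndarray,
    diagonal_sqrt2: bool = False,
) -> Iterator[SubCatchment]:
    """One SubCatchment per stream cell, in row-major outlet order."""
    streams = np.asarray(streams, dtype=bool)
    start, donors = _donor_adjacency(fd)
    for r, c in np.argwhere(streams):
        yield _build_subcatchment(
            fd, streams, start, donors, (int(r), int(c)), diagonal_sqrt2
        )


def delineate_all(
    fd: FlowDirectionGrid,
    streams: np.ndarray,
    chunk_size: int = 10_000,
    diagonal_sqrt2: bool = False,
) -> Iterator[list[SubCatchment]]:
    """Stream of sub-catchments grouped in chunks of ``chunk_size``.

    Chunking mirrors the batched production layout (compressed bundles of
    10,000 watershed files); chunks are independent work units and are
    yielded in deterministic row-major outlet order.
    """
    if chunk_size < 1:
        raise InvalidParameterError("chunk_size must be >= 1")
    chunk: list[SubCatchment] = []
    for sc in iter_subcatchments(fd, streams, diagonal_sqrt2):
        chunk.append(sc)
        if len(chunk) == chunk_size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk
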