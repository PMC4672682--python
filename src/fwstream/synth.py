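"""Deterministic synthetic fixtures: terrain, climate layers, minimal networks, lakes.

Every generator here is a pure function of its explicit arguments and seed,
so the whole processing chain can be exercised — and its outputs checked
against independent oracles — without downloading any real hydrography or
climate data.

The valley DEM emulates a single drainage basin (the role the void-filled
SRTM-derived DEM plays in production): a tilted V-shaped surface descending
to one outlet cell on the southern edge, with optional seeded noise on the
interior so depression filling has real work to do.  The environmental
layer generator emulates the source-layer families (constant fields, smooth
north-south gradients, seeded random fields, and land-cover class fractions
that sum to 100 per cell).  Lake masks are unions of rectangular blobs.

Minimal Strahler networks
-------------------------
``make_minimal_order_network(k)`` returns the smallest drainage network this
generator can embed on a D8 grid whose outlet attains Strahler order ``k``.
The combinatorial minimum is 2**k - 1 cells (each confluence merges two
minimal order-(k-1) trees).  That minimum is *achievable on a grid only for
k <= 6*: a complete binary merge tree of depth k-1 with every donor
8-adjacent to its recipient must pack 2**k - 1 distinct cells inside
Chebyshev radius k-1 of the outlet, and 2**k - 1 > (2k-1)**2 already for
k >= 8; exhaustive search shows depth 6 (k = 7) is likewise infeasible.
Exact embeddings for k <= 6, found once by search, are frozen below.  For
k >= 7 two order-(k-1) networks are joined through shortest connector
reaches, so the cell count exceeds 2**k - 1; the count is still the
generator's deterministic minimum-effort layout and the outlet order is
exactly ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidSpecError
from .grid import (
    D8_OFFSETS,
    FD_NODATA,
    SINK,
    ElevationGrid,
    EnvGrid,
    FlowDirectionGrid,
    GridGeometry,
    default_geometry,
)

__all__ = [
    "SyntheticBasinSpec",
    "make_valley_dem",
    "make_env_layer",
    "make_minimal_order_network",
    "make_lake_mask",
]


@dataclass(frozen=True)
class SyntheticBasinSpec:
    """Specification of a synthetic single-outlet drainage basin.

    ``relief`` is the total elevation drop (m) along the valley axis;
    ``noise_amplitude`` bounds the uniform noise added to interior cells and
    must stay below ``relief / nrows`` so noise cannot out-compete the
    along-valley gradient and create spurious edge outlets.
    """

    nrows: int
    ncols: int
    relief: float = 100.0
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nrows < 3 or self.ncols < 3:
            raise InvalidSpecError(
                f"basin must be at least 3x3, got {self.nrows}x{self.ncols}"
            )
        if self.relief <= 0:
            raise InvalidSpecError("relief must be positive")
        if self.noise_amplitude < 0:
            raise InvalidSpecError("noise amplitude must be non-negative")
        if self.noise_amplitude >= self.relief / self.nrows:
            raise InvalidSpecError(
                "noise_amplitude must be < relief/nrows to preserve drainage"
            )

    @property
    def outlet(self) -> tuple[int, int]:
        """The designated edge outlet: middle of the southern edge."""
        return (self.nrows - 1, self.ncols // 2)


def make_valley_dem(spec: SyntheticBasinSpec) -> ElevationGrid:
    """V-shaped valley draining to a single cell on the southern edge.

    The analytic surface is ``relief * (along-valley drop) + 0.25 * relief *
    (cross-valley distance)`` with the global minimum at ``spec.outlet``.
    Seeded uniform noise is added to interior cells only, keeping the
    boundary analytic so the outlet remains the unique edge sink; any pits
    the noise creates are for :func:`~fwstream.hydrology.fill_depressions`
    to resolve.  Identical specs produce bit-identical grids.
    """
    nrows, ncols = spec.nrows, spec.ncols
    _, c_out = spec.outlet
    rows = np.arange(nrows, dtype=float)[:, None]
    cols = np.arange(ncols, dtype=float)[None, :]
    along = (nrows - 1 - rows) / (nrows - 1)
    cross = np.abs(cols - c_out) / max(1, ncols - 1)
    z = spec.relief * along + 0.25 * spec.relief * cross

    if spec.noise_amplitude > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.uniform(-spec.noise_amplitude, spec.noise_amplitude, size=(nrows, ncols))
        interior = np.zeros((nrows, ncols), dtype=bool)
        interior[1:-1, 1:-1] = True
        z = z + np.where(interior, noise, 0.0)

    return ElevationGrid(
        values=z,
        geometry=default_geometry(nrows, ncols),
        nodata=None,
        units="m",
    )


def make_env_layer(
    shape: tuple[int, int],
    kind: str,
    params: dict | None = None,
    seed: int = 0,
) -> EnvGrid | list[EnvGrid]:
    """Synthetic environmental source layer(s).

    kind:
      ``constant``        — all cells equal ``params['value']`` (default 0).
      ``gradient``        — linear in row index from ``params['top']`` at the
                            northern edge to ``params['bottom']`` at the south.
      ``random``          — seeded uniform field in [``low``, ``high``).
      ``class_fractions`` — ``params['n_classes']`` (default 12) integer
                            layers that sum to exactly 100 in every cell,
                            the land-cover percent-cover contract.
    """
    params = dict(params or {})
    geometry = default_geometry(*shape)

    if kind == "constant":
        value = float(params.get("value", 0.0))
        return EnvGrid(np.full(shape, value), geometry=geometry)
    if kind == "gradient":
        top = float(params.get("top", 0.0))
        bottom = float(params.get("bottom", 1.0))
        rows = np.linspace(top, bottom, shape[0])[:, None]
        return EnvGrid(np.broadcast_to(rows, shape).copy(), geometry=geometry)
    if kind == "random":
        low = float(params.get("low", 0.0))
        high = float(params.get("high", 1.0))
        rng = np.random.default_rng(seed)
        return EnvGrid(rng.uniform(low, high, size=shape), geometry=geometry)
    if kind == "class_fractions":
        n_classes = int(params.get("n_classes", 12))
        rng = np.random.default_rng(seed)
        # Dirichlet-ish integer split: random weights, largest-remainder rounding
        w = rng.random(size=(n_classes,) + tuple(shape)) + 1e-9
        frac = 100.0 * w / w.sum(axis=0)
        floors = np.floor(frac).astype(np.int64)
        deficit = 100 - floors.sum(axis=0)
        remainder = frac - floors
        rank = np.argsort(-remainder, axis=0, kind="stable")
        for k in range(n_classes):
            floors[rank[k], np.indices(shape)[0], np.indices(shape)[1]] += (
                k < deficit
            ).astype(np.int64)
        assert (floors.sum(axis=0) == 100).all(), "class fractions must sum to 100"
        assert (floors >= 0).all()
        return [
            EnvGrid(floors[i], geometry=geometry, units="%") for i in range(n_classes)
        ]
    raise InvalidSpecError(f"unknown layer kind {kind!r}")


# ---------------------------------------------------------------------------
# Minimal Strahler-order networks
# ---------------------------------------------------------------------------
# Exact minimal embeddings of the complete binary merge tree, found by
# exhaustive backtracking in the 8-neighbour king graph.  Each entry is
# (cell, downstream-cell) in tree coordinates; the root drains to None.
# Depth d gives outlet order d+1 with exactly 2**(d+1) - 1 cells.
_EXACT_TREES: dict[int, list[tuple[tuple[int, int], tuple[int, int] | None]]] = {
    0: [((0, 0), None)],
    1: [((0, 0), None), ((0, 1), (0, 0)), ((1, 1), (0, 0))],
    2: [((0, 0), None), ((0, 1), (0, 0)), ((1, 1), (0, 0)), ((0, 2), (0, 1)),
        ((1, 2), (0, 1)), ((2, 2), (1, 1)), ((2, 1), (1, 1))],
    3: [((0, 0), None), ((0, 1), (0, 0)), ((1, 1), (0, 0)), ((0, 2), (0, 1)),
        ((1, 2), (0, 1)), ((0, 3), (0, 2)), ((1, 3), (0, 2)), ((2, 3), (1, 2)),
        ((2, 2), (1, 2)), ((2, 1), (1, 1)), ((2, 0), (1, 1)), ((3, 2), (2, 1)),
        ((3, 1), (2, 1)), ((3, 0), (2, 0)), ((3, -1), (2, 0))],
    4: [((0, 0), None), ((0, 1), (0, 0)), ((1, 1), (0, 0)), ((0, 2), (0, 1)),
        ((1, 2), (0, 1)), ((0, 3), (0, 2)), ((1, 3), (0, 2)), ((0, 4), (0, 3)),
        ((1, 4), (0, 3)), ((2, 4), (1, 3)), ((2, 3), (1, 3)), ((2, 2), (1, 2)),
        ((2, 1), (1, 2)), ((3, 3), (2, 2)), ((3, 2), (2, 2)), ((3, 1), (2, 1)),
        ((3, 0), (2, 1)), ((2, 0), (1, 1)), ((1, 0), (1, 1)), ((3, -1), (2, 0)),
        ((2, -1), (2, 0)), ((4, 0), (3, -1)), ((4, -1), (3, -1)), ((3, -2), (2, -1)),
        ((2, -2), (2, -1)), ((1, -1), (1, 0)), ((0, -1), (1, 0)), ((1, -2), (1, -1)),
        ((0, -2), (1, -1)), ((-1, -2), (0, -1)), ((-1, -1), (0, -1))],
    5: [((0, 0), None), ((0, 1), (0, 0)), ((1, 1), (0, 0)), ((0, 2), (0, 1)),
        ((-1, 2), (0, 1)), ((0, 3), (0, 2)), ((1, 3), (0, 2)), ((0, 4), (0, 3)),
        ((1, 4), (0, 3)), ((0, 5), (0, 4)), ((1, 5), (0, 4)), ((2, 5), (1, 4)),
        ((2, 4), (1, 4)), ((2, 3), (1, 3)), ((2, 2), (1, 3)), ((3, 4), (2, 3)),
        ((3, 3), (2, 3)), ((3, 2), (2, 2)), ((3, 1), (2, 2)), ((-1, 3), (-1, 2)),
        ((-2, 3), (-1, 2)), ((-1, 4), (-1, 3)), ((-2, 4), (-1, 3)), ((-1, 5), (-1, 4)),
        ((-2, 5), (-1, 4)), ((-3, 5), (-2, 4)), ((-3, 4), (-2, 4)), ((-3, 2), (-2, 3)),
        ((-3, 3), (-2, 3)), ((-4, 1), (-3, 2)), ((-4, 2), (-3, 2)), ((-4, 3), (-3, 3)),
        ((-4, 4), (-3, 3)), ((2, 1), (1, 1)), ((1, 0), (1, 1)), ((3, 0), (2, 1)),
        ((2, 0), (2, 1)), ((4, 1), (3, 0)), ((4, 0), (3, 0)), ((5, 2), (4, 1)),
        ((5, 1), (4, 1)), ((5, 0), (4, 0)), ((5, -1), (4, 0)), ((3, -1), (2, 0)),
        ((2, -1), (2, 0)), ((4, -1), (3, -1)), ((4, -2), (3, -1)), ((3, -2), (2, -1)),
        ((2, -2), (2, -1)), ((1, -1), (1, 0)), ((0, -1), (1, 0)), ((1, -2), (1, -1)),
        ((0, -2), (1, -1)), ((2, -3), (1, -2)), ((1, -3), (1, -2)), ((0, -3), (0, -2)),
        ((-1, -3), (0, -2)), ((-1, -2), (0, -1)), ((-1, -1), (0, -1)),
        ((-2, -3), (-1, -2)), ((-2, -2), (-1, -2)), ((-2, -1), (-1, -1)),
        ((-2, 0), (-1, -1))],
}

_MAX_EXACT_ORDER = 6


def _tree_edges(k: int) -> tuple[dict[tuple[int, int], tuple[int, int] | None], tuple[int, int]]:
    """cell -> downstream-cell map and outlet for the order-k network."""
    if k <= _MAX_EXACT_ORDER:
        edges = dict(_EXACT_TREES[k - 1])
        return edges, (0, 0)
    left, l_out = _tree_edges(k - 1)
    right, r_out = _tree_edges(k - 1)

    def bbox(cells):
        rs = [r for r, _ in cells]
        cs = [c for _, c in cells]
        return min(rs), max(rs), min(cs), max(cs)

    r0, r1, c0, c1 = bbox(left)
    height, width = r1 - r0 + 1, c1 - c0 + 1

    def shift(edges_in, dr, dc):
        return {
            (r + dr, c + dc): (None if d is None else (d[0] + dr, d[1] + dc))
            for (r, c), d in edges_in.items()
        }

    # normalise both copies to rows [0, height); right copy east of a
    # 3-column gap so connector reaches have room to run
    left_n = shift(left, -r0, -c0)
    l_out = (l_out[0] - r0, l_out[1] - c0)
    right_n = shift(right, -r0, -c0 + width + 3)
    r_out = (r_out[0] - r0, r_out[1] - c0 + width + 3)

    merged = {**left_n, **right_n}
    confluence = (height + 2, width + 1)

    def connect(start: tuple[int, int], occupied: set) -> list[tuple[int, int]]:
        """Deterministic BFS shortest king-graph path start -> confluence
        through empty cells (endpoints excluded from the path returned)."""
        from collections import deque

        lo_r, hi_r = -2, height + 4
        lo_c, hi_c = -2, 2 * width + 5
        prev: dict[tuple[int, int], tuple[int, int]] = {start: start}
        queue = deque([start])
        while queue:
            cur = queue.popleft()
            if cur == confluence:
                path = []
                node = prev[confluence]
                while node != start:
                    path.append(node)
                    node = prev[node]
                path.reverse()
                return path
            for dr, dc in D8_OFFSETS:
                nxt = (cur[0] + dr, cur[1] + dc)
                if not (lo_r <= nxt[0] <= hi_r and lo_c <= nxt[1] <= hi_c):
                    continue
                if nxt in prev or (nxt in occupied and nxt != confluence):
                    continue
                prev[nxt] = cur
                queue.append(nxt)
        raise AssertionError("connector path not found (generator bug)")

    occupied = set(merged)
    l_path = connect(l_out, occupied)
    occupied |= set(l_path) | {confluence}
    r_path = connect(r_out, occupied)

    for start, path in ((l_out, l_path), (r_out, r_path)):
        chain = [start, *path, confluence]
        for a, b in zip(chain, chain[1:]):
            merged[a] = b
    merged[confluence] = None
    return merged, confluence


def make_minimal_order_network(k: int) -> tuple[FlowDirectionGrid, np.ndarray]:
    """Smallest embeddable drainage network whose outlet has Strahler order ``k``.

    Returns a flow-direction grid (network cells only; everything else
    NoData, the outlet a sink) and the matching stream mask.  For
    ``k <= 6`` the network has exactly ``2**k - 1`` cells — the theoretical
    minimum; for ``k >= 7`` connector reaches make it larger (see module
    docstring).
    """
    if not 1 <= k <= 9:
        raise InvalidSpecError(f"order must be in 1..9, got {k}")
    edges, outlet = _tree_edges(k)

    rows = [r for r, _ in edges]
    cols = [c for _, c in edges]
    r0, c0 = min(rows) - 1, min(cols) - 1
    nrows = max(rows) - min(rows) + 3
    ncols = max(cols) - min(cols) + 3

    codes = np.full((nrows, ncols), FD_NODATA, dtype=np.int8)
    offset_code = {off: i for i, off in enumerate(D8_OFFSETS)}
    for (r, c), downstream in edges.items():
        rr, cc = r - r0, c - c0
        if downstream is None:
            codes[rr, cc] = SINK
        else:
            dr, dc = downstream[0] - r, downstream[1] - c
            codes[rr, cc] = offset_code[(dr, dc)]

    streams = codes != FD_NODATA
    fd = FlowDirectionGrid(codes=codes, geometry=default_geometry(nrows, ncols))
    return fd, streams


def make_lake_mask(
    shape: tuple[int, int],
    blobs: list[tuple[int, int, int, int]] | None = None,
    seed: int = 0,
    n_random: int = 0,
    blob_size: tuple[int, int] = (2, 4),
) -> np.ndarray:
    """Boolean lake/reservoir mask from rectangular blobs.

    ``blobs`` are explicit (row, col, height, width) rectangles (clipped to
    the grid); ``n_random`` adds seeded random rectangles with side lengths
    drawn from ``blob_size``.  Overlapping blobs merge into one connected
    region under any connectivity.
    """
    mask = np.zeros(shape, dtype=bool)
    for r, c, h, w in blobs or []:
        mask[max(0, r): r + h, max(0, c): c + w] = True
    if n_random:
        rng = np.random.default_rng(seed)
        for _ in range(n_random):
            h = int(rng.integers(blob_size[0], blob_size[1] + 1))
            w = int(rng.integers(blob_size[0], blob_size[1] + 1))
            r = int(rng.integers(0, max(1, shape[0] - h)))
            c = int(rng.integers(0, max(1, shape[1] - w)))
            mask[r: r + h, c: c + w] = True
    return mask


def count_connected_regions(mask: np.ndarray, connectivity: int = 4) -> int:
    """Connected components in a boolean mask (used by fixture oracles)."""
    structure = (
        ndimage.generate_binary_structure(2, 2)
        if connectivity == 8
        else ndimage.generate_binary_structure(2, 1)
    )
    _, n = ndimage.label(mask, structure=structure)
    return int(n)
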