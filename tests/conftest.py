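"""Shared fixtures and independent oracles.

The oracles deliberately avoid the library's own graph machinery: catchment
membership is decided by following each cell's downstream pointer chain,
accumulation by counting path hits, so they can arbitrate the BFS/topological
implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from fwstream.grid import D8_OFFSETS, FlowDirectionGrid
from fwstream.hydrology import (
    extract_streams,
    fill_depressions,
    flow_accumulation,
    flow_direction,
    strahler,
)
from fwstream.synth import SyntheticBasinSpec, make_valley_dem


@pytest.fixture(scope="session")
def basin32():
    """A routed noisy 32x32 single-outlet basin with streams and orders."""
    spec = SyntheticBasinSpec(32, 32, relief=150.0, noise_amplitude=3.0, seed=11)
    dem = make_valley_dem(spec)
    fd = flow_direction(fill_depressions(dem))
    acc = flow_accumulation(fd)
    streams = extract_streams(acc, threshold=20)
    order = strahler(fd, streams)
    return {"spec": spec, "dem": dem, "fd": fd, "acc": acc,
            "streams": streams, "order": order}


def routed_basin(nrows, ncols, seed, noise=2.0, relief=150.0, threshold=20):
    spec = SyntheticBasinSpec(nrows, ncols, relief=relief,
                              noise_amplitude=noise, seed=seed)
    fd = flow_direction(fill_depressions(make_valley_dem(spec)))
    acc = flow_accumulation(fd)
    return spec, fd, acc, extract_streams(acc, threshold=threshold)


def make_chain_fd(n: int) -> FlowDirectionGrid:
    """A 1 x n grid where every cell flows east into its neighbour."""
    from fwstream.grid import SINK, default_geometry

    codes = np.zeros((1, n), dtype=np.int8)  # E
    codes[0, -1] = SINK
    return FlowDirectionGrid(codes=codes, geometry=default_geometry(1, n))


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def downstream_map(fd: FlowDirectionGrid) -> np.ndarray:
    """Flat downstream pointer computed directly from the D8 codes."""
    nrows, ncols = fd.shape
    down = np.full(nrows * ncols, -1, dtype=np.int64)
    for r in range(nrows):
        for c in range(ncols):
            code = fd.codes[r, c]
            if code < 0:
                continue
            dr, dc = D8_OFFSETS[code]
            nr, nc = r + dr, c + dc
            if 0 <= nr < nrows and 0 <= nc < ncols:
                down[r * ncols + c] = nr * ncols + nc
    return down


def path_membership_oracle(fd: FlowDirectionGrid, outlet) -> set[tuple[int, int]]:
    """Follow every cell's flow path and test whether it hits the outlet."""
    nrows, ncols = fd.shape
    down = downstream_map(fd)
    target = outlet[0] * ncols + outlet[1]
    pos = np.arange(nrows * ncols)
    valid = fd.valid.ravel()
    hit = valid & (pos == target)
    for _ in range(nrows * ncols):  # longest possible path
        moved = down[np.where(pos >= 0, pos, 0)]
        pos = np.where(pos >= 0, moved, -1)
        hit |= valid & (pos == target)
        if (pos < 0).all():
            break
    idx = np.nonzero(hit)[0]
    return {(int(i // ncols), int(i % ncols)) for i in idx}


def accumulation_oracle(fd: FlowDirectionGrid) -> np.ndarray:
    """Count, for every cell, how many cells' paths pass through it."""
    nrows, ncols = fd.shape
    down = downstream_map(fd)
    counts = np.zeros(nrows * ncols, dtype=np.int64)
    valid = fd.valid.ravel()
    for start in np.nonzero(valid)[0]:
        cur = start
        while cur >= 0:
            counts[cur] += 1
            cur = down[cur]
    return counts.reshape(nrows, ncols)


def naive_bioclim(tmin, tmax, prec):
    """Straightforward scalar re-implementation of the 19 bioclim variables."""
    tmin, tmax, prec = (list(map(float, x)) for x in (tmin, tmax, prec))
    tavg = [(a + b) / 2 for a, b in zip(tmin, tmax)]
    quarters = [[(i + j) % 12 for j in range(3)] for i in range(12)]
    qt = [sum(tavg[m] for m in q) / 3 for q in quarters]
    qp = [sum(prec[m] for m in q) for q in quarters]

    def argbest(vals, best):
        target = best(vals)
        return min(i for i, v in enumerate(vals) if v == target)

    bio = {}
    bio[1] = sum(tavg) / 12
    bio[2] = sum(b - a for a, b in zip(tmin, tmax)) / 12
    bio[5] = max(tmax)
    bio[6] = min(tmin)
    bio[7] = bio[5] - bio[6]
    bio[3] = 100 * bio[2] / bio[7] if bio[7] != 0 else 0.0
    mean_t = bio[1]
    bio[4] = 100 * (sum((t - mean_t) ** 2 for t in tavg) / 12) ** 0.5
    bio[8] = qt[argbest(qp, max)]
    bio[9] = qt[argbest(qp, min)]
    bio[10] = qt[argbest(qt, max)]
    bio[11] = qt[argbest(qt, min)]
    bio[12] = sum(prec)
    bio[13] = max(prec)
    bio[14] = min(prec)
    mean_p = bio[12] / 12
    sd_p = (sum((p - mean_p) ** 2 for p in prec) / 12) ** 0.5
    bio[15] = 100 * sd_p / (1 + bio[12] / 12)
    bio[16] = qp[argbest(qp, max)]
    bio[17] = qp[argbest(qp, min)]
    bio[18] = qp[argbest(qt, max)]
    bio[19] = qp[argbest(qt, min)]
    return [bio[i] for i in range(1, 20)]
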