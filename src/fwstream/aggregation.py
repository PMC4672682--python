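"""Upstream summary metrics and integer storage scaling.

For each stream cell, the environmental conditions of its sub-catchment are
condensed to a scalar with one of seven metrics:

    min, max, range, average, sum, weighted_average, weighted_sum

computed over one of two domains:

``catchment``
    every cell of the sub-catchment, with straight-line distances and
    weights (used for precipitation, land cover, soil, geology);
``watercourse``
    the sub-catchment's stream cells only, with along-network distances and
    weights (used for temperature and the temperature-based hydro-climatic
    variables).

Weighted metrics use w = 1/d: weighted_average = sum(w*v)/sum(w) and
weighted_sum = sum(w*v).  NoData cells in the source layer are ignored; if
the whole domain is NoData the result is NoData (never an exception).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, InvalidParameterError, RangeError
from .grid import EnvGrid, FlowDirectionGrid, Raster
from .subcatchment import SubCatchment, iter_subcatchments

__all__ = ["MetricSpec", "aggregate", "build_variable", "scale_store", "METRICS", "DOMAINS"]

METRICS = ("min", "max", "range", "average", "sum", "weighted_average", "weighted_sum")
DOMAINS = ("catchment", "watercourse")


@dataclass(frozen=True)
class MetricSpec:
    """Which statistic to take over which upstream domain."""

    metric: str
    domain: str = "catchment"

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise InvalidParameterError(f"unknown metric {self.metric!r}")
        if self.domain not in DOMAINS:
            raise InvalidParameterError(f"unknown domain {self.domain!r}")


def aggregate(sc: SubCatchment, layer: EnvGrid, spec: MetricSpec) -> float:
    """Summarise ``layer`` over the sub-catchment's domain cells.

    Returns NaN when every domain cell is NoData in the layer.
    """
    cells = sc.cells
    if spec.domain == "watercourse":
        sel = sc.is_stream
        weights = sc.w_network[sel]
    else:
        sel = np.ones(len(cells), dtype=bool)
        weights = sc.w_euclid

    rr, cc = cells[sel, 0], cells[sel, 1]
    vals = layer.values[rr, cc].astype(float)
    ok = layer.valid[rr, cc]
    if not ok.any():
        return float("nan")
    vals = vals[ok]
    w = np.asarray(weights, dtype=float)[ok]

    if spec.metric == "min":
        return float(vals.min())
    if spec.metric == "max":
        return float(vals.max())
    if spec.metric == "range":
        return float(vals.max() - vals.min())
    if spec.metric == "average":
        return float(vals.mean())
    if spec.metric == "sum":
        return float(vals.sum())
    if spec.metric == "weighted_average":
        return float((w * vals).sum() / w.sum())
    return float((w * vals).sum())  # weighted_sum


def build_variable(
    fd: FlowDirectionGrid,
    streams: np.ndarray,
    layer: EnvGrid,
    spec: MetricSpec,
    nodata: float = -9999.0,
    diagonal_sqrt2: bool = False,
) -> EnvGrid:
    """Apply :func:`aggregate` at every stream cell; NoData elsewhere.

    This is the whole-network variant used for single layers; the CLI's
    pipeline reuses pre-delineated sub-catchments to aggregate many layers
    in one pass instead.
    """
    streams = np.asarray(streams, dtype=bool)
    if layer.shape != fd.shape:
        raise GeometryError("layer geometry does not match flow grid")
    out = np.full(fd.shape, nodata, dtype=float)
    for sc in iter_subcatchments(fd, streams, diagonal_sqrt2):
        val = aggregate(sc, layer, spec)
        out[sc.outlet] = nodata if np.isnan(val) else val
    return layer.with_values(out, nodata=nodata)


_STORAGE_BOUNDS = {
    "Byte": (-128, 127),
    "Int16": (-(2**15), 2**15 - 1),
    "Int32": (-(2**31), 2**31 - 1),
    "Float64": (None, None),
}


def scale_store(value: float, factor: int = 1, storage: str = "Int32") -> float | int:
    """Scale and truncate a value for integer storage.

    Temperatures are stored x10 and slopes x100 to keep integer rasters
    small; decimals are truncated toward zero (not rounded).  NaN passes
    through so the caller can substitute the catalog NoData code.
    Float64 storage applies no truncation.
    """
    if factor < 1:
        raise InvalidParameterError(f"scale factor must be >= 1, got {factor}")
    if storage not in _STORAGE_BOUNDS:
        raise InvalidParameterError(f"unknown storage type {storage!r}")
    if isinstance(value, float) and np.isnan(value):
        return value
    scaled = value * factor
    if storage == "Float64":
        return float(scaled)
    stored = int(scaled)  # int() truncates toward zero
    lo, hi = _STORAGE_BOUNDS[storage]
    if not (lo <= stored <= hi):
        raise RangeError(f"{value} * {factor} does not fit {storage}")
    return stored


def scale_store_grid(variable: Raster, factor: int, storage: str, nodata: float) -> Raster:
    """Vectorised :func:`scale_store` over a raster, writing catalog NoData."""
    vals = variable.masked() * factor
    if storage == "Float64":
        out = np.where(np.isnan(vals), nodata, vals)
        return variable.with_values(out, nodata=nodata)
    lo, hi = _STORAGE_BOUNDS[storage]
    trunc = np.trunc(vals)
    finite = ~np.isnan(trunc)
    if finite.any() and ((trunc[finite] < lo).any() or (trunc[finite] > hi).any()):
        raise RangeError(f"scaled values overflow {storage}")
    out = np.where(finite, trunc, float(nodata)).astype(
        np.int8 if storage == "Byte" else np.int32 if storage != "Float64" else float
    )
    return variable.with_values(out, nodata=nodata)
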