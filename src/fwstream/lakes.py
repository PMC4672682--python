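"""Extending stream variables across lakes and reservoirs.

Rasterised lakes appear in a routed 1 km hydrography as "fish-bone"
patterns: parallel artificial flow lines crossing the water body.  To mimic
the more static environment of standing water, each lake/reservoir that is
connected to the stream network receives the mean of the stream-cell values
inside it, and the step between in-lake and in-stream values at the
shoreline is smoothed with a 3x3 window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError
from .grid import EnvGrid

__all__ = ["LakeUnit", "label_lakes", "lake_average", "smooth_interface"]


@dataclass
class LakeUnit:
    """One connected lake/reservoir: maximal connected component of the mask."""

    unit_id: int
    cells: np.ndarray            # (n, 2) row/col indices
    intersects_stream: bool


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise InvalidParameterError(f"connectivity must be 4 or 8, got {connectivity}")


def label_lakes(
    mask: np.ndarray,
    streams: np.ndarray | None = None,
    connectivity: int = 4,
    min_cells: int = 1,
) -> list[LakeUnit]:
    """Label connected lake units; drop units smaller than ``min_cells``.

    Connectivity 4 is the clumping default; the released product's source
    filter (">0.1 km^2 surface area") acts on sub-cell polygons before
    rasterisation and maps here onto the ``min_cells`` parameter.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    streams = None if streams is None else np.asarray(streams, dtype=bool)
    units: list[LakeUnit] = []
    for uid in range(1, n + 1):
        cells = np.argwhere(labels == uid)
        if len(cells) < min_cells:
            continue
        hits = bool(streams[cells[:, 0], cells[:, 1]].any()) if streams is not None else False
        units.append(LakeUnit(unit_id=uid, cells=cells, intersects_stream=hits))
    return units


def lake_average(
    variable: EnvGrid, units: list[LakeUnit], streams: np.ndarray
) -> EnvGrid:
    """Spread each connected unit's mean stream value over the whole unit.

    Only units touching the stream network receive values (averaged over
    the unit's valued cells — in a routed hydrography the fish-bone stream
    cells are the only cells inside a lake that carry values).  Units with
    no valued cell stay NoData; cells outside lakes are unchanged.
    Applying the operation twice equals applying it once.
    """
    streams = np.asarray(streams, dtype=bool)
    if streams.shape != variable.shape:
        raise GeometryError("stream mask does not match variable grid")
    out = variable.values.astype(float, copy=True)
    valid = variable.valid
    nodata = variable.nodata if variable.nodata is not None else np.nan
    for unit in units:
        rr, cc = unit.cells[:, 0], unit.cells[:, 1]
        if not streams[rr, cc].any():
            continue
        vals = out[rr, cc]
        ok = valid[rr, cc]
        if ok.any():
            out[rr, cc] = vals[ok].mean()
        else:
            out[rr, cc] = nodata
    return variable.with_values(out)


def smooth_interface(
    variable: EnvGrid,
    units: list[LakeUnit],
    streams: np.ndarray,
    window: int = 3,
) -> EnvGrid:
    """Average across the stream/lake shoreline.

    Cells at the interface — lake cells 8-adjacent to a stream cell outside
    the lake, and stream cells 8-adjacent to a lake cell — are replaced by
    the mean of the valued cells in their ``window x window`` neighbourhood,
    removing steep artificial steps.  All other cells are unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise InvalidParameterError(f"window must be an odd integer >= 3, got {window}")
    streams = np.asarray(streams, dtype=bool)
    lake = np.zeros(variable.shape, dtype=bool)
    for unit in units:
        lake[unit.cells[:, 0], unit.cells[:, 1]] = True

    eight = ndimage.generate_binary_structure(2, 2)
    near_lake = ndimage.binary_dilation(lake, structure=eight)
    near_stream = ndimage.binary_dilation(streams & ~lake, structure=eight)
    interface = (lake & near_stream) | (streams & ~lake & near_lake)

    vals = variable.masked()
    ok = ~np.isnan(vals)
    total = ndimage.uniform_filter(np.where(ok, vals, 0.0), size=window,
                                   mode="constant") * window**2
    count = np.round(
        ndimage.uniform_filter(ok.astype(float), size=window, mode="constant")
        * window**2
    )
    out = variable.values.astype(float, copy=True)
    sel = interface & (count > 0)
    out[sel] = total[sel] / count[sel]
    return variable.with_values(out)
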