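"""Quality control: truncated-sub-catchment detection and repair.

A stream cell whose upstream flow accumulation is implausibly small for its
Strahler order marks a truncated sub-catchment (broken routing at basin
margins, coasts, or data-edge cells).  The minimum plausible accumulation
follows the Strahler hierarchy: an order-k cell needs two order-(k-1)
tributaries, so at least ``2**k - 1`` upstream cells (3, 7, 15, 31, 63,
127, 255, 511 for orders 2-9; order-1 cells need only themselves).

Flagged cells are repaired by iteratively assigning the maximum value of
the unflagged same-order cells in their 3x3 neighbourhood — the maximum,
because a truncated catchment *underestimates* its upstream summary — until
a fixpoint.  Cells that cannot be repaired (no same-order valued neighbour
reachable) are reported, not raised.  A user-supplied removal mask (the
manually-identified counterpart of overestimated cells) is applied last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import GeometryError, InvalidParameterError
from .grid import EnvGrid, Raster

__all__ = ["QCReport", "min_cells", "flag_truncated", "fill_flagged", "apply_removal_mask"]


@dataclass
class QCReport:
    flagged: np.ndarray                      # boolean grid of initially flagged cells
    filled_per_iteration: list[int] = field(default_factory=list)
    unresolved: np.ndarray | None = None     # boolean grid
    removed: np.ndarray | None = None        # boolean grid

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def n_unresolved(self) -> int:
        return 0 if self.unresolved is None else int(self.unresolved.sum())


def min_cells(order: int) -> int:
    """Minimum upstream cell count consistent with a Strahler order.

    1 for order 1, else ``2**order - 1`` (two minimal order-(k-1) trees
    plus the confluence cell).
    """
    if order < 1:
        raise InvalidParameterError(f"Strahler order must be >= 1, got {order}")
    return 1 if order == 1 else 2**order - 1


def flag_truncated(acc: Raster, order: Raster) -> np.ndarray:
    """Stream cells whose accumulation is below the order's minimum."""
    if acc.shape != order.shape:
        raise GeometryError("accumulation and order grids differ in shape")
    flags = np.zeros(acc.shape, dtype=bool)
    on_stream = order.valid & (order.values >= 1)
    ks = np.unique(order.values[on_stream])
    for k in ks:
        sel = on_stream & (order.values == k)
        flags[sel] = acc.values[sel] < min_cells(int(k))
    return flags


def fill_flagged(
    variable: EnvGrid,
    flags: np.ndarray,
    order: Raster,
    max_iter: int = 50,
    window: int = 3,
) -> tuple[EnvGrid, QCReport]:
    """Iteratively repair flagged cells from same-order neighbours.

    Each iteration, every still-flagged cell that has at least one
    *unflagged* valued cell of the same Strahler order inside its
    ``window x window`` neighbourhood takes the maximum of those values and
    becomes unflagged.  Donor values are frozen at the start of each
    iteration, so repairs propagate one neighbourhood per pass.  Iteration
    stops at a fixpoint or after ``max_iter`` passes; leftover cells are
    reported as unresolved.
    """
    flags = np.asarray(flags, dtype=bool).copy()
    if flags.shape != variable.shape:
        raise GeometryError("flag mask does not match variable grid")
    initial = flags.copy()
    vals = variable.masked()
    footprint = np.ones((window, window), dtype=bool)

    per_iter: list[int] = []
    for _ in range(max_iter):
        if not flags.any():
            break
        donors_ok = (~flags) & ~np.isnan(vals)
        filled_this_round = np.zeros_like(flags)
        new_vals = vals.copy()
        for k in np.unique(order.values[flags & order.valid]):
            donors = np.where(donors_ok & (order.values == k), vals, -np.inf)
            local_max = ndimage.maximum_filter(donors, footprint=footprint,
                                               mode="constant", cval=-np.inf)
            target = flags & (order.values == k) & np.isfinite(local_max)
            new_vals[target] = local_max[target]
            filled_this_round |= target
        n = int(filled_this_round.sum())
        if n == 0:  # fixpoint: the empty terminal pass is not tallied
            break
        per_iter.append(n)
        vals = new_vals
        flags &= ~filled_this_round

    nodata = variable.nodata
    out = vals
    if nodata is not None:
        out = np.where(np.isnan(vals), nodata, vals)
    report = QCReport(flagged=initial, filled_per_iteration=per_iter,
                      unresolved=flags)
    return variable.with_values(out), report


def apply_removal_mask(
    variables: dict[str, EnvGrid], removal: np.ndarray
) -> dict[str, EnvGrid]:
    """Blank the manually-flagged cells in every layer.

    Each masked cell is set to the layer's own NoData code; the mask itself
    is exported separately (the catalog's ``cells_removed`` band) so users
    can identify the omitted reaches.
    """
    removal = np.asarray(removal, dtype=bool)
    out: dict[str, EnvGrid] = {}
    for code, layer in variables.items():
        if removal.shape != layer.shape:
            raise GeometryError(f"removal mask does not match layer {code!r}")
        vals = layer.values.copy()
        nodata = layer.nodata if layer.nodata is not None else np.nan
        if np.issubdtype(vals.dtype, np.integer) and layer.nodata is None:
            vals = vals.astype(float)
        vals[removal] = nodata
        out[code] = layer.with_values(vals)
    return out
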