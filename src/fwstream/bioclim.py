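"""The 19 bioclim hydro-climatic variables from monthly climate normals.

Given 12 monthly minimum temperatures, maximum temperatures (deg C) and
precipitation sums (mm), the standard 19 derived variables are:

====  ==========================================================
bio1  annual mean temperature: mean of monthly (tmin+tmax)/2
bio2  mean diurnal range: mean of monthly (tmax - tmin)
bio3  isothermality: 100 * bio2 / bio7
bio4  temperature seasonality: 100 * population SD of monthly means
bio5  max temperature of warmest month
bio6  min temperature of coldest month
bio7  annual temperature range: bio5 - bio6
bio8  mean temperature of wettest quarter
bio9  mean temperature of driest quarter
bio10 mean temperature of warmest quarter
bio11 mean temperature of coldest quarter
bio12 annual precipitation
bio13 precipitation of wettest month
bio14 precipitation of driest month
bio15 precipitation seasonality: 100 * SD(prec) / (1 + bio12/12)
bio16 precipitation of wettest quarter
bio17 precipitation of driest quarter
bio18 precipitation of warmest quarter
bio19 precipitation of coldest quarter
====  ==========================================================

Quarters are the twelve wrap-around 3-month windows (Jan-Feb-Mar, ...,
Dec-Jan-Feb); ties between windows resolve to the earliest.  bio15 uses the
1 + bio12/12 denominator so arid cells (zero annual precipitation) stay
finite; pass ``simple_mean_denominator=True`` for the plain mean variant.
bio3 is defined as 0 where bio7 is 0 (constant temperature all year).

In the stream-variable pipeline these are computed per stream cell *after*
the monthly layers have been aggregated upstream, i.e. from each cell's 36
upstream-summarised monthly values.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidParameterError

__all__ = ["bioclim19", "BIOCLIM_NAMES"]

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))


def _as_months(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[0] != 12:
        raise InvalidParameterError(f"{name} must have 12 monthly values along axis 0")
    return arr


def bioclim19(
    tmin,
    tmax,
    prec,
    simple_mean_denominator: bool = False,
) -> np.ndarray:
    """Compute the 19 bioclim variables.

    Inputs may be shape (12,) for one site or (12, ...) for stacked sites;
    the result has shape (19,) or (19, ...) correspondingly.
    """
    tmin = _as_months(tmin, "tmin")
    tmax = _as_months(tmax, "tmax")
    prec = _as_months(prec, "prec")
    if not (tmin.shape == tmax.shape == prec.shape):
        raise InvalidParameterError("tmin, tmax and prec shapes must agree")

    tavg = (tmin + tmax) / 2.0

    # wrap-around 3-month windows, window i = months (i, i+1, i+2) mod 12
    idx = (np.arange(12)[:, None] + np.arange(3)[None, :]) % 12
    q_t = tavg[idx].mean(axis=1)   # (12, ...) quarterly mean temperature
    q_p = prec[idx].sum(axis=1)    # (12, ...) quarterly precipitation

    # argmax/argmin return the first (earliest window) on ties
    wettest = np.argmax(q_p, axis=0)
    driest = np.argmin(q_p, axis=0)
    warmest = np.argmax(q_t, axis=0)
    coldest = np.argmin(q_t, axis=0)

    take = np.take_along_axis
    bio = np.empty((19,) + tavg.shape[1:], dtype=float)
    bio[0] = tavg.mean(axis=0)
    bio[1] = (tmax - tmin).mean(axis=0)
    bio[4] = tmax.max(axis=0)
    bio[5] = tmin.min(axis=0)
    bio[6] = bio[4] - bio[5]
    with np.errstate(invalid="ignore", divide="ignore"):
        bio[2] = np.where(bio[6] != 0, 100.0 * bio[1] / bio[6], 0.0)
    bio[3] = 100.0 * tavg.std(axis=0)  # population SD
    bio[7] = take(q_t, wettest[None], axis=0)[0]
    bio[8] = take(q_t, driest[None], axis=0)[0]
    bio[9] = take(q_t, warmest[None], axis=0)[0]
    bio[10] = take(q_t, coldest[None], axis=0)[0]
    bio[11] = prec.sum(axis=0)
    bio[12] = prec.max(axis=0)
    bio[13] = prec.min(axis=0)
    denom = prec.mean(axis=0) if simple_mean_denominator else 1.0 + bio[11] / 12.0
    with np.errstate(invalid="ignore", divide="ignore"):
        bio[14] = np.where(denom != 0, 100.0 * prec.std(axis=0) / denom, 0.0)
    bio[15] = take(q_p, wettest[None], axis=0)[0]
    bio[16] = take(q_p, driest[None], axis=0)[0]
    bio[17] = take(q_p, warmest[None], axis=0)[0]
    bio[18] = take(q_p, coldest[None], axis=0)[0]
    return bio
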