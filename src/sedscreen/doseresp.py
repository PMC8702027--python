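"""Concentration-response modeling and point-of-departure derivation.

Responses are first scaled to the vehicle (solvent-only) control mean,
then fit with a four-parameter Hill/logistic curve in log10 dilution:

    f(x) = bottom + (top - bottom) / (1 + 10^(hill * (log10_ec50 - log10 x)))

The point of departure (POD) is the smallest tested dilution at which
the fitted curve exits the vehicle band (vehicle mean +/- one vehicle
SD).  Crossings are solved from the logistic inverse where possible and
by bracketed root finding otherwise.  Curves that never leave the band
over the tested range are censored at the maximum tested dilution;
crossings below the lowest tested dilution are clamped there and
flagged "extrapolated-low".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .errors import DegenerateControlError, InsufficientDataError
from .synth import VEHICLE_ID

__all__ = [
    "VehicleStats", "LogisticFit", "POD",
    "logistic4", "vehicle_stats", "scale_to_vehicle",
    "fit_logistic", "derive_pod", "fit_pods",
]


@dataclass(frozen=True)
class VehicleStats:
    endpoint_id: str
    mean: float
    sd: float
    n_wells: int

    def __post_init__(self):
        if self.n_wells < 2:
            raise InsufficientDataError(
                f"{self.endpoint_id}: need >= 2 vehicle wells, got {self.n_wells}")
        if self.sd < 0:
            raise ValueError("vehicle sd must be nonnegative")


@dataclass(frozen=True)
class LogisticFit:
    bottom: float
    top: float
    log10_ec50: float
    hill: float  # signed: positive when response rises with concentration
    converged: bool
    rss: float

    def __call__(self, dilution):
        return logistic4(dilution, self.bottom, self.top,
                         self.log10_ec50, abs(self.hill))


@dataclass(frozen=True)
class POD:
    sample_id: str
    endpoint_id: str
    value: float      # dilution fraction of stock
    censored: bool
    direction: str    # "above" | "below" | "none"
    flag: str = ""    # "", "extrapolated-low", "nonconverged"


def logistic4(dilution, bottom, top, log10_ec50, hill):
    """Four-parameter logistic in log10 dilution (hill > 0; direction is
    carried by top vs bottom)."""
    logd = np.log10(dilution)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log10_ec50 - logd)))


# ---------------------------------------------------------------------------
# vehicle scaling
# ---------------------------------------------------------------------------

def vehicle_stats(plates: pd.DataFrame, endpoint_id: str) -> VehicleStats:
    """Pooled vehicle-well statistics for one endpoint."""
    wells = plates.loc[
        (plates["sample_id"] == VEHICLE_ID) & (plates["endpoint_id"] == endpoint_id),
        "response",
    ].values
    if wells.size < 2:
        raise InsufficientDataError(
            f"{endpoint_id}: found {wells.size} vehicle wells, need >= 2")
    return VehicleStats(endpoint_id, float(np.mean(wells)),
                        float(np.std(wells, ddof=1)), int(wells.size))


def scale_to_vehicle(raw_responses: np.ndarray, stats: VehicleStats) -> np.ndarray:
    """Divide responses by the vehicle mean; the vehicle band becomes
    1 +/- sd/mean."""
    if stats.mean == 0:
        raise DegenerateControlError(
            f"{stats.endpoint_id}: vehicle mean is zero; series unusable")
    return np.asarray(raw_responses, float) / stats.mean


# ---------------------------------------------------------------------------
# curve fitting
# ---------------------------------------------------------------------------

_HILL_BOUNDS = (0.05, 8.0)


def fit_logistic(dilutions: Sequence[float], responses: Sequence[float],
                 n_starts: int = 5) -> LogisticFit:
    """Least-squares 4PL fit with multi-start EC50 initialization.

    ``dilutions`` and ``responses`` are flat, aligned arrays (replicates
    repeated).  Flat series return a flat fit (top == bottom) with
    converged=True.  Among converged starts the lowest RSS wins, ties
    broken by the smaller |hill|.
    """
    d = np.asarray(dilutions, float)
    y = np.asarray(responses, float)
    if d.size != y.size or d.size == 0:
        raise InsufficientDataError("dilutions and responses must align and be non-empty")
    if np.unique(d).size < 4:
        raise InsufficientDataError("need >= 4 distinct dilutions")
    if np.ptp(y) == 0.0:
        return LogisticFit(float(y[0]), float(y[0]), float(np.log10(np.median(d))),
                           _HILL_BOUNDS[0], True, 0.0)

    logd = np.log10(d)
    lo, hi = logd.min(), logd.max()
    span = float(np.ptp(y))
    ylo, yhi = y.min() - 2 * span - 0.5, y.max() + 2 * span + 0.5
    order = np.argsort(logd)
    # responses near the low- and high-concentration ends seed bottom/top
    k = max(1, d.size // 8)
    b0 = float(np.mean(y[order[:k]]))
    t0 = float(np.mean(y[order[-k:]]))

    ln10 = math.log(10.0)

    def resid(p):
        bottom, top, ec50, hill = p
        return logistic4(d, bottom, top, ec50, hill) - y

    def jac(p):
        bottom, top, ec50, hill = p
        u = 10.0 ** (hill * (ec50 - logd))
        sig = 1.0 / (1.0 + u)
        common = (top - bottom) * (-ln10) * u * sig ** 2
        return np.column_stack([
            1.0 - sig,
            sig,
            common * hill,
            common * (ec50 - logd),
        ])

    bounds = ([ylo, ylo, lo - 2.0, _HILL_BOUNDS[0]],
              [yhi, yhi, hi + 2.0, _HILL_BOUNDS[1]])
    best = None
    for ec0 in np.linspace(lo, hi, n_starts):
        x0 = np.clip([b0, t0, ec0, 1.5], bounds[0], bounds[1])
        try:
            res = least_squares(resid, x0, jac=jac, bounds=bounds, method="trf",
                                xtol=1e-10, ftol=1e-10, gtol=1e-10,
                                max_nfev=200)
        except Exception:
            continue
        rss = float(np.sum(res.fun ** 2))
        cand = (rss, abs(res.x[3]), res)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return LogisticFit(b0, t0, 0.5 * (lo + hi), 1.0, False, float("inf"))
    rss, _, res = best
    bottom, top, ec50, hill = (float(v) for v in res.x)
    signed_hill = hill if top >= bottom else -hill
    return LogisticFit(bottom, top, ec50, signed_hill, bool(res.success), rss)


# ---------------------------------------------------------------------------
# POD derivation
# ---------------------------------------------------------------------------

def _crossing(fit: LogisticFit, threshold: float) -> Optional[float]:
    """log10 dilution where the fitted curve equals ``threshold``
    (logistic inverse); None when no solution exists."""
    bottom, top, hill = fit.bottom, fit.top, abs(fit.hill)
    if top == bottom:
        return None
    ratio = (top - threshold) / (threshold - bottom)
    if ratio <= 0 or not math.isfinite(ratio):
        return None
    return fit.log10_ec50 - math.log10(ratio) / hill


def derive_pod(fit: LogisticFit, stats: VehicleStats,
               tested_range: Sequence[float],
               sample_id: str = "", scaled: bool = True) -> POD:
    """POD = smallest tested dilution where |f(x) - vehicle mean| > sd.

    ``scaled`` indicates the fit is on vehicle-scaled data (vehicle mean
    1, band sd/mean); otherwise the raw stats are used directly.
    """
    dmin, dmax = float(min(tested_range)), float(max(tested_range))
    eid = stats.endpoint_id
    if not fit.converged:
        return POD(sample_id, eid, dmax, True, "none", "nonconverged")
    if stats.mean == 0:
        raise DegenerateControlError(f"{eid}: vehicle mean is zero")
    vm = 1.0 if scaled else stats.mean
    sd = stats.sd / abs(stats.mean) if scaled else stats.sd

    def exceeds(logx):
        return abs(float(fit(10.0 ** logx)) - vm) > sd

    lmin, lmax = math.log10(dmin), math.log10(dmax)
    eps = 1e-9

    def direction_at(logx):
        return "above" if float(fit(10.0 ** logx)) > vm else "below"

    if exceeds(lmin + eps):
        return POD(sample_id, eid, dmin, False, direction_at(lmin + eps),
                   "extrapolated-low")

    # analytic candidates from the logistic inverse, bisection fallback
    candidates = []
    for t in (vm + sd, vm - sd):
        c = _crossing(fit, t)
        if c is not None and lmin < c <= lmax:
            candidates.append(c)
        elif fit.top != fit.bottom:
            # numeric fallback when the inverse is ill-conditioned
            g = lambda lx, t=t: float(fit(10.0 ** lx)) - t
            if g(lmin) * g(lmax) < 0:
                try:
                    candidates.append(brentq(g, lmin, lmax, xtol=1e-12, rtol=1e-10))
                except ValueError:
                    pass
    for c in sorted(set(candidates)):
        step = max(eps, abs(c) * 1e-9)
        if c + step <= lmax and exceeds(c + step):
            return POD(sample_id, eid, 10.0 ** c, False, direction_at(c + step))
    if exceeds(lmax):
        # departs only at the top point (numerical corner): clamp to dmax
        return POD(sample_id, eid, dmax, False, direction_at(lmax))
    return POD(sample_id, eid, dmax, True, "none")


# ---------------------------------------------------------------------------
# plate-table pipeline
# ---------------------------------------------------------------------------

def fit_pods(plates: pd.DataFrame) -> pd.DataFrame:
    """Fit every sample x endpoint series in a long plate table.

    Expects columns sample_id, endpoint_id, cell_type, dilution,
    replicate, response with vehicle wells under sample_id "VEHICLE".
    Returns one row per sample x endpoint with the POD, censoring flag,
    direction and fit diagnostics.
    """
    out = []
    cell_types = (plates.drop_duplicates("endpoint_id")
                  .set_index("endpoint_id")["cell_type"].to_dict())
    treated = plates[plates["sample_id"] != VEHICLE_ID]
    for eid, sub in treated.groupby("endpoint_id", sort=True):
        stats = vehicle_stats(plates, eid)
        for sid, series in sub.groupby("sample_id", sort=True):
            d = series["dilution"].values
            y = scale_to_vehicle(series["response"].values, stats)
            fit = fit_logistic(d, y)
            pod = derive_pod(fit, stats, (d.min(), d.max()), sample_id=sid)
            out.append({
                "sample_id": sid,
                "endpoint_id": eid,
                "cell_type": cell_types.get(eid, ""),
                "pod": pod.value,
                "censored": pod.censored,
                "direction": pod.direction,
                "flag": pod.flag,
                "bottom": fit.bottom,
                "top": fit.top,
                "log10_ec50": fit.log10_ec50,
                "hill": fit.hill,
                "rss": fit.rss,
                "converged": fit.converged,
                "vehicle_mean": stats.mean,
                "vehicle_sd": stats.sd,
            })
    return pd.DataFrame(out).sort_values(["sample_id", "endpoint_id"]).reset_index(drop=True)
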