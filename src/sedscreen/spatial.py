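"""Spatial association tests and geostatistical interpolation.

Two tools:

* A Mantel-type permutation test comparing pairwise geographic
  distances (haversine, km) against feature dissimilarities — squared
  differences for a single feature, 1 - Spearman correlation of feature
  vectors for a global test.  The statistic is the Pearson correlation
  of the upper-triangle entries; the null is generated by simultaneous
  row/column permutation of the feature matrix; the one-sided (greater)
  p-value is (1 + #{perm >= observed}) / (B + 1).  Benjamini-Hochberg
  adjustment is applied across features.

* Ordinary kriging with a spherical semivariogram fit by weighted least
  squares to the method-of-moments empirical semivariogram, with
  optional log10 transform of the data, producing predictions and
  kriging variances on a regular lon/lat grid.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, InsufficientDataError, ZeroVarianceError

EARTH_RADIUS_KM = 6371.0088

__all__ = [
    "haversine_km", "geo_distances", "feature_distances",
    "MantelResult", "mantel_test", "mantel_screen", "bh_adjust",
    "Variogram", "empirical_semivariogram", "fit_spherical",
    "krige_points", "krige",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 lon/lat points."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geo_distances(sites: pd.DataFrame) -> pd.DataFrame:
    """Symmetric haversine distance matrix (km) from a sites table with
    sample_id, lon, lat columns."""
    ids = sites["sample_id"].values
    lon, lat = sites["lon"].values, sites["lat"].values
    d = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=ids, columns=ids)


def feature_distances(values, mode: str = "squared_diff",
                      ids: Optional[Sequence] = None) -> pd.DataFrame:
    """Feature dissimilarity matrix.

    mode="squared_diff": ``values`` is one feature per sample; entries
    are (v_i - v_j)^2.  mode="one_minus_spearman": ``values`` is a
    samples x features matrix; entries are 1 - Spearman correlation of
    the two samples' feature vectors (range [0, 2]).
    """
    if mode == "squared_diff":
        if isinstance(values, pd.Series):
            ids = values.index if ids is None else ids
            v = values.values.astype(float)
        else:
            v = np.asarray(values, float)
        d = (v[:, None] - v[None, :]) ** 2
    elif mode == "one_minus_spearman":
        if isinstance(values, pd.DataFrame):
            ids = values.index if ids is None else ids
            m = values.values.astype(float)
        else:
            m = np.asarray(values, float)
        if m.ndim != 2 or m.shape[1] < 2:
            raise InsufficientDataError("global mode needs >= 2 features")
        ranks = np.apply_along_axis(rankdata, 1, m)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        norm = np.sqrt((ranks ** 2).sum(axis=1))
        if np.any(norm == 0):
            raise ZeroVarianceError("a sample has constant feature ranks")
        rho = (ranks @ ranks.T) / np.outer(norm, norm)
        d = 1.0 - rho
        np.fill_diagonal(d, 0.0)
    else:
        raise ConfigurationError(f"unknown feature-distance mode {mode!r}")
    ids = np.arange(d.shape[0]) if ids is None else ids
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    feature_id: str
    statistic: float
    p_value: float
    n_perm: int
    p_adj: float = math.nan


def _triu(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ZeroVarianceError("distance triangle has zero variance")
    return float(xc @ yc) / denom


def mantel_test(d_geo: pd.DataFrame, d_feat: pd.DataFrame,
                n_perm: int = 10000, seed: Optional[int] = None,
                exhaustive: bool = False,
                feature_id: str = "") -> MantelResult:
    """One-sided (greater) Mantel permutation test.

    With ``exhaustive=True`` all n! relabelings (including the identity)
    are enumerated and p is the exact fraction with statistic >= the
    observed one; otherwise ``n_perm`` Monte-Carlo permutations are used
    with p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if list(d_geo.index) != list(d_feat.index):
        d_feat = d_feat.loc[d_geo.index, d_geo.index]
    g = d_geo.values.astype(float)
    f = d_feat.values.astype(float)
    n = g.shape[0]
    if n < 4:
        raise InsufficientDataError("Mantel test needs >= 4 samples")
    x = _triu(g)
    obs = _pearson(x, _triu(f))
    xc = x - x.mean()
    xnorm = math.sqrt(float(xc @ xc))

    def stat(perm) -> float:
        fp = f[np.ix_(perm, perm)]
        y = _triu(fp)
        yc = y - y.mean()
        ynorm = math.sqrt(float(yc @ yc))
        return float(xc @ yc) / (xnorm * ynorm)

    if exhaustive:
        stats = [stat(list(p)) for p in itertools.permutations(range(n))]
        p = float(np.mean(np.asarray(stats) >= obs - 1e-12))
        return MantelResult(feature_id, obs, p, len(stats))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(n)) >= obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(feature_id, obs, p, n_perm)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def mantel_screen(sites: pd.DataFrame, features: pd.DataFrame,
                  n_perm: int = 10000, seed: Optional[int] = None,
                  include_global: bool = True) -> pd.DataFrame:
    """Mantel test for every feature column plus an optional global
    (1 - Spearman) test; BH adjustment across the per-feature tests.

    Feature columns with zero variance are reported with NaN statistics
    rather than raising.
    """
    d_geo = geo_distances(sites)
    ids = sites["sample_id"].values
    feats = features.loc[ids]
    rows = []
    ss = np.random.SeedSequence(seed).spawn(feats.shape[1] + 1)
    for k, col in enumerate(feats.columns):
        sub = int(ss[k].generate_state(1)[0] % (2 ** 31))
        try:
            d_feat = feature_distances(feats[col], mode="squared_diff", ids=ids)
            r = mantel_test(d_geo, d_feat, n_perm=n_perm, seed=sub,
                            feature_id=str(col))
            rows.append({"feature": str(col), "statistic": r.statistic,
                         "p": r.p_value, "n_perm": r.n_perm})
        except ZeroVarianceError:
            rows.append({"feature": str(col), "statistic": math.nan,
                         "p": math.nan, "n_perm": n_perm})
    out = pd.DataFrame(rows)
    ok = out["p"].notna()
    out["p_adj"] = math.nan
    out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].values)
    if include_global:
        sub = int(ss[-1].generate_state(1)[0] % (2 ** 31))
        d_feat = feature_distances(feats, mode="one_minus_spearman", ids=ids)
        r = mantel_test(d_geo, d_feat, n_perm=n_perm, seed=sub,
                        feature_id="__global__")
        out = pd.concat([out, pd.DataFrame([{
            "feature": "__global__", "statistic": r.statistic,
            "p": r.p_value, "n_perm": r.n_perm, "p_adj": r.p_value,
        }])], ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# variogram + ordinary kriging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Variogram:
    """Spherical semivariogram: gamma(h) = nugget + psill * (1.5 h/a -
    0.5 (h/a)^3) for h <= a, sill beyond the range a."""

    nugget: float
    sill: float    # total sill (nugget + partial sill)
    range_km: float
    lag_size: float = math.nan

    def __post_init__(self):
        if self.nugget < 0 or self.sill < self.nugget or self.range_km <= 0:
            raise ConfigurationError("require 0 <= nugget <= sill and range > 0")

    def gamma(self, h):
        h = np.asarray(h, float)
        psill = self.sill - self.nugget
        hr = np.minimum(h / self.range_km, 1.0)
        g = self.nugget + psill * (1.5 * hr - 0.5 * hr ** 3)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h):
        """C(h) = sill - gamma(h); C(0) = sill."""
        return self.sill - self.gamma(h)


def empirical_semivariogram(d: np.ndarray, values: np.ndarray,
                            lag_size: float, max_lag: Optional[float] = None):
    """Method-of-moments semivariogram: per lag bin, mean of squared
    increments / 2.  Returns (lag centers, gamma, pair counts)."""
    iu = np.triu_indices(d.shape[0], 1)
    h = d[iu]
    sq = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if max_lag is None:
        max_lag = float(h.max()) / 2
    nbins = max(1, int(math.ceil(max_lag / lag_size)))
    lags, gammas, counts = [], [], []
    for b in range(nbins):
        mask = (h >= b * lag_size) & (h < (b + 1) * lag_size)
        if mask.sum() == 0:
            continue
        lags.append((b + 0.5) * lag_size)
        gammas.append(float(sq[mask].mean()))
        counts.append(int(mask.sum()))
    return np.array(lags), np.array(gammas), np.array(counts)


def fit_spherical(lags: np.ndarray, gammas: np.ndarray,
                  counts: np.ndarray, lag_size: float = math.nan) -> Variogram:
    """Weighted least-squares spherical model fit (weights = pair counts)."""
    var0 = float(gammas.max()) if gammas.size else 1.0
    var0 = max(var0, 1e-12)
    rng0 = float(lags.max()) if lags.size else 1.0

    def model(h, nugget, psill, a):
        hr = np.minimum(h / a, 1.0)
        return nugget + psill * (1.5 * hr - 0.5 * hr ** 3)

    try:
        popt, _ = curve_fit(
            model, lags, gammas,
            p0=[0.0, var0, max(rng0 / 2, 1e-6)],
            sigma=1.0 / np.sqrt(counts),
            bounds=([0.0, 1e-12, 1e-6], [var0 * 2 + 1e-9, var0 * 3 + 1e-9, rng0 * 4 + 1.0]),
            maxfev=20000,
        )
        nugget, psill, a = (float(v) for v in popt)
    except Exception:
        nugget, psill, a = 0.0, var0, max(rng0 / 2, 1e-6)
    return Variogram(nugget=nugget, sill=nugget + psill, range_km=a,
                     lag_size=lag_size)


def _dedupe(sites: pd.DataFrame, values: np.ndarray):
    coords = np.column_stack([sites["lon"].values, sites["lat"].values])
    key = np.round(coords, 9)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    if np.all(counts == 1):
        return coords, values
    warnings.warn("duplicate site coordinates: averaging values", stacklevel=3)
    uniq = np.unique(inv)
    out_c = np.array([key[inv == u][0] for u in uniq])
    out_v = np.array([values[inv == u].mean() for u in uniq])
    return out_c, out_v


def krige_points(sites: pd.DataFrame, values, targets: np.ndarray,
                 variogram: Variogram, log10_transform: bool = True,
                 return_weights: bool = False):
    """Ordinary kriging predictions at arbitrary lon/lat target points.

    Solves the ordinary-kriging system (covariance form, Lagrange
    multiplier for the unbiasedness constraint sum(w) = 1) once with the
    site matrix factorized for all targets.  Returns (predictions,
    kriging variances[, weights]); predictions are back-transformed when
    ``log10_transform``.
    """
    v = np.asarray(values, float)
    if log10_transform:
        if np.any(v <= 0):
            raise ConfigurationError("log transform requires positive values")
        v = np.log10(v)
    coords, v = _dedupe(sites, v)
    n = coords.shape[0]
    if n < 5:
        raise InsufficientDataError("kriging needs >= 5 sites")
    d = haversine_km(coords[:, 0][:, None], coords[:, 1][:, None],
                     coords[:, 0][None, :], coords[:, 1][None, :])
    a = np.empty((n + 1, n + 1))
    a[:n, :n] = variogram.covariance(d)
    a[:n, n] = 1.0
    a[n, :n] = 1.0
    a[n, n] = 0.0
    targets = np.asarray(targets, float)
    dt = haversine_km(coords[:, 0][:, None], coords[:, 1][:, None],
                      targets[:, 0][None, :], targets[:, 1][None, :])
    b = np.empty((n + 1, targets.shape[0]))
    b[:n] = variogram.covariance(dt)
    b[n] = 1.0
    sol = np.linalg.solve(a, b)
    w, mu = sol[:n], sol[n]
    pred = w.T @ v
    var = variogram.sill - np.einsum("ij,ij->j", w, b[:n]) - mu
    if log10_transform:
        pred = 10.0 ** pred
    if return_weights:
        return pred, var, w.T
    return pred, var


def krige(sites: pd.DataFrame, values, grid: tuple = (100, 100),
          margin: float = 0.05, lag_size_km: float = 2.0,
          variogram: Optional[Variogram] = None,
          log10_transform: bool = True):
    """Krige a feature onto a regular lon/lat grid over the site
    bounding box (+``margin`` fractional padding).

    Fits the spherical variogram to the (optionally log10) data unless
    one is supplied.  Returns (grid DataFrame with lon, lat, prediction,
    kriging_variance, Variogram).
    """
    v = np.asarray(values, float)
    work = np.log10(v) if log10_transform else v
    if log10_transform and np.any(v <= 0):
        raise ConfigurationError("log transform requires positive values")
    if variogram is None:
        coords, wv = _dedupe(sites, work)
        d = haversine_km(coords[:, 0][:, None], coords[:, 1][:, None],
                         coords[:, 0][None, :], coords[:, 1][None, :])
        lags, gammas, counts = empirical_semivariogram(d, wv, lag_size_km)
        variogram = fit_spherical(lags, gammas, counts, lag_size=lag_size_km)
    lon, lat = sites["lon"].values, sites["lat"].values
    dlon = (lon.max() - lon.min()) * margin or 0.01
    dlat = (lat.max() - lat.min()) * margin or 0.01
    gx = np.linspace(lon.min() - dlon, lon.max() + dlon, grid[0])
    gy = np.linspace(lat.min() - dlat, lat.max() + dlat, grid[1])
    gg = np.array([(x, y) for y in gy for x in gx])
    pred, var = krige_points(sites, values, gg, variogram,
                             log10_transform=log10_transform)
    out = pd.DataFrame({"lon": gg[:, 0], "lat": gg[:, 1],
                        "prediction": pred, "kriging_variance": var})
    return out, variogram
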