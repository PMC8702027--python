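"""Chemistry <-> bioactivity cross-prediction.

A multivariate ridge regression with a single shared penalty predicts
every column of one feature matrix (e.g. the 34 bioactivity features)
from the other (e.g. the 40 chemical measurements), evaluated by
leave-one-out cross-validation: the held-out sample's row is removed
from both matrices before any standardization or fitting, columns are
standardized on the training fold, the ridge solution is computed for
all response columns at once, and the held-out prediction is returned
to the original scale with the training fold's column mean and SD.  The
penalty is chosen on a log-spaced grid to minimize the overall
(fold-standardized) mean-squared prediction error.

Per-feature significance is the Pearson correlation between the
cross-validated predictions and the observed values, with a two-sided
p-value and Benjamini-Hochberg adjustment across features.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError
from .spatial import bh_adjust

__all__ = [
    "CrossPredResult", "default_lambda_grid", "loocv_ridge",
    "prediction_significance", "cross_predict",
    "prepare_bio_matrix", "prepare_chem_matrix",
]


@dataclass
class CrossPredResult:
    predicted: pd.DataFrame          # original scale, same shape as target
    lambda_: float
    lambda_grid: np.ndarray
    cv_mse: np.ndarray               # standardized-scale MSE per grid lambda
    mse: float                       # at the chosen lambda
    feature_stats: Optional[pd.DataFrame] = None
    dropped_features: list = field(default_factory=list)


def default_lambda_grid(n_features: int, n_points: int = 30) -> np.ndarray:
    """Log-spaced grid over [1e-3, 1e3] scaled by the predictor count."""
    return np.logspace(-3, 3, n_points) * n_features


def _standardize(m: np.ndarray):
    mu = m.mean(axis=0)
    sd = m.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (m - mu) / sd_safe, mu, sd, sd_safe


def loocv_ridge(X: pd.DataFrame, Y: pd.DataFrame,
                lambda_grid: Optional[np.ndarray] = None,
                seed: Optional[int] = None) -> CrossPredResult:
    """Leave-one-out cross-validated multivariate ridge.

    ``seed`` is accepted for interface uniformity; LOOCV is
    deterministic.  All-constant response columns are excluded with a
    warning.  Per fold the SVD of the standardized predictor block is
    reused across the whole penalty grid.
    """
    if list(X.index) != list(Y.index):
        Y = Y.loc[X.index]
    n = X.shape[0]
    if n < 5:
        raise InsufficientDataError("LOOCV ridge needs >= 5 samples")
    keep = [c for c in Y.columns if Y[c].nunique() > 1]
    dropped = [c for c in Y.columns if c not in keep]
    if dropped:
        warnings.warn(f"dropping constant response columns: {dropped}", stacklevel=2)
    Yk = Y[keep]
    Xv, Yv = X.values.astype(float), Yk.values.astype(float)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X.shape[1])
    lambda_grid = np.asarray(lambda_grid, float)

    n_lam = lambda_grid.size
    pred_std_err = np.zeros((n_lam, n, Yv.shape[1]))  # standardized residuals
    pred_orig = np.zeros((n_lam, n, Yv.shape[1]))
    for i in range(n):
        tr = np.ones(n, bool)
        tr[i] = False
        Xs, mux, _, sdx = _standardize(Xv[tr])
        Ys, muy, sdy, sdy_safe = _standardize(Yv[tr])
        u, s, vt = np.linalg.svd(Xs, full_matrices=False)
        uty = u.T @ Ys
        x0 = (Xv[i] - mux) / sdx
        proj = vt @ x0  # components of the held-out row in the right basis
        y0_std = (Yv[i] - muy) / sdy_safe
        for k, lam in enumerate(lambda_grid):
            shrink = s / (s ** 2 + lam)
            yhat_std = (proj * shrink) @ uty
            pred_std_err[k, i] = yhat_std - y0_std
            pred_orig[k, i] = yhat_std * sdy + muy
    cv_mse = (pred_std_err ** 2).mean(axis=(1, 2))
    best = int(np.argmin(cv_mse))
    predicted = pd.DataFrame(pred_orig[best], index=X.index, columns=keep)
    return CrossPredResult(
        predicted=predicted,
        lambda_=float(lambda_grid[best]),
        lambda_grid=lambda_grid,
        cv_mse=cv_mse,
        mse=float(cv_mse[best]),
        dropped_features=dropped,
    )


def prediction_significance(predicted: pd.DataFrame,
                            actual: pd.DataFrame,
                            alternative: str = "greater") -> pd.DataFrame:
    """Per-feature Pearson r between cross-validated predictions and
    observations, BH-adjusted across features.

    The test is one-sided (greater) by default: predictive skill means
    positive correlation, and cross-validated predictions of signal-free
    features are systematically *anti*-correlated with the held-out
    values (shrinkage toward the training mean), an artifact a two-sided
    test would flag as significant.  Degenerate (constant) predictions
    are flagged and reported as non-significant (r = NaN, p = 1).
    """
    actual = actual.loc[predicted.index]
    rows = []
    for col in predicted.columns:
        yhat = predicted[col].values
        y = actual[col].values
        if np.std(yhat) == 0 or np.std(y) == 0:
            rows.append({"feature": col, "r": math.nan, "p": 1.0,
                         "degenerate": True})
            continue
        r, p = sps.pearsonr(yhat, y, alternative=alternative)
        rows.append({"feature": col, "r": float(r), "p": float(p),
                     "degenerate": False})
    out = pd.DataFrame(rows)
    out["p_adj"] = bh_adjust(out["p"].values)
    return out


def cross_predict(X: pd.DataFrame, Y: pd.DataFrame,
                  lambda_grid: Optional[np.ndarray] = None,
                  seed: Optional[int] = None) -> CrossPredResult:
    """LOOCV ridge prediction of Y from X plus per-feature significance.

    Symmetric API: call with (chem, bio) or (bio, chem)."""
    res = loocv_ridge(X, Y, lambda_grid=lambda_grid, seed=seed)
    res.feature_stats = prediction_significance(res.predicted, Y[res.predicted.columns])
    return res


# ---------------------------------------------------------------------------
# matrix preparation
# ---------------------------------------------------------------------------

def prepare_bio_matrix(pods: pd.DataFrame) -> pd.DataFrame:
    """Bioactivity feature matrix: log10 POD per sample x endpoint;
    censored entries enter at the maximum tested dilution value."""
    mat = pods.pivot(index="sample_id", columns="endpoint_id", values="pod")
    return np.log10(mat)


def prepare_chem_matrix(chem: pd.DataFrame) -> pd.DataFrame:
    """Chemistry feature matrix: log10(x + half the minimum positive
    value per column)."""
    out = {}
    for col in chem.columns:
        v = chem[col].values.astype(float)
        pos = v[v > 0]
        off = pos.min() / 2 if pos.size else 1.0
        out[col] = np.log10(v + off)
    return pd.DataFrame(out, index=chem.index)
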