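"""ToxPi integration of POD matrices.

Per-endpoint PODs are inversely scaled to [0, 1] slice scores: the
highest POD (least potent sample) maps to 0 and the lowest POD (most
potent) to 1, by default on the log10 scale within each endpoint.
Censored PODs (no observed bioactivity) score 0.  Slice scores are
aggregated to per-cell-type means and an overall weighted mean, samples
are ranked (rank 1 = highest overall score), and rows/columns are
ordered by average-linkage hierarchical clustering for heatmap display.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .errors import ConfigurationError

__all__ = ["scale_pods", "aggregate", "cluster_order", "toxpi_from_pods"]


def _pivot(pods: pd.DataFrame, column: str) -> pd.DataFrame:
    return pods.pivot(index="sample_id", columns="endpoint_id", values=column)


def scale_pods(pods: pd.DataFrame, per_endpoint: bool = True,
               log_scale: bool = True) -> pd.DataFrame:
    """Inverse-scale a long POD table to [0, 1] slice scores.

    Expects columns sample_id, endpoint_id, pod, censored.  Active PODs
    are scored (max - pod) / (max - pod range) on the log10 (default) or
    linear scale, with the extrema taken per endpoint (default) or over
    the pooled dataset; censored entries score 0, as do endpoints whose
    active PODs span zero range.
    """
    vals = _pivot(pods, "pod")
    cens = _pivot(pods, "censored").astype(bool)
    t = np.log10(vals.values) if log_scale else vals.values
    active = ~cens.values & np.isfinite(t)
    scores = np.zeros_like(t, dtype=float)
    if per_endpoint:
        for j in range(t.shape[1]):
            aj = active[:, j]
            if not aj.any():
                continue
            hi, lo = np.nanmax(t[aj, j]), np.nanmin(t[aj, j])
            if hi == lo:
                continue
            scores[aj, j] = (hi - t[aj, j]) / (hi - lo)
    else:
        if active.any():
            hi, lo = np.nanmax(t[active]), np.nanmin(t[active])
            if hi != lo:
                scores[active] = (hi - t[active]) / (hi - lo)
    return pd.DataFrame(scores, index=vals.index, columns=vals.columns)


def aggregate(slice_scores: pd.DataFrame,
              cell_types: Mapping[str, str],
              weights: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Aggregate slice scores to cell-type means, overall score and rank.

    ``cell_types`` maps endpoint_id -> cell type; ``weights`` optional
    nonnegative per-endpoint weights (default equal).  Rank 1 is the
    highest overall score; ties keep input order.
    """
    cols = list(slice_scores.columns)
    if weights is None:
        w = np.ones(len(cols))
    else:
        w = np.array([float(weights.get(c, 1.0)) for c in cols])
        if np.any(w < 0):
            raise ConfigurationError("slice weights must be nonnegative")
    if w.sum() == 0:
        raise ConfigurationError("at least one slice weight must be positive")
    out = pd.DataFrame(index=slice_scores.index)
    for ct in sorted(set(cell_types.values())):
        members = [c for c in cols if cell_types.get(c) == ct]
        if members:
            out[f"celltype_{ct}"] = slice_scores[members].mean(axis=1)
    out["overall"] = slice_scores.values @ (w / w.sum())
    order = np.lexsort((np.arange(len(out)), -out["overall"].values))
    rank = np.empty(len(out), dtype=int)
    rank[order] = np.arange(1, len(out) + 1)
    out["rank"] = rank
    return pd.concat([slice_scores, out], axis=1)


def cluster_order(matrix: pd.DataFrame) -> tuple:
    """Average-linkage (Euclidean) leaf orders for rows and columns.

    Deterministic given the input; single-row/column axes return the
    identity order.
    """
    def order_axis(m: np.ndarray) -> list:
        if m.shape[0] <= 1:
            return list(range(m.shape[0]))
        z = linkage(m, method="average", metric="euclidean")
        return [int(i) for i in leaves_list(z)]

    m = matrix.values.astype(float)
    return order_axis(m), order_axis(m.T)


def toxpi_from_pods(pods: pd.DataFrame, per_endpoint: bool = True,
                    log_scale: bool = True,
                    weights: Optional[Mapping[str, float]] = None) -> pd.DataFrame:
    """Full ToxPi table (slices + cell-type scores + overall + rank)
    from a long POD table carrying a cell_type column."""
    cell_types = (pods.drop_duplicates("endpoint_id")
                  .set_index("endpoint_id")["cell_type"].to_dict())
    scores = scale_pods(pods, per_endpoint=per_endpoint, log_scale=log_scale)
    return aggregate(scores, cell_types, weights=weights)
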