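"""Traditional versus bioactivity-based remediation goals.

Because HI, CR, and endpoint activity are all monotone in concentration,
a remediation goal can be expressed as a fold-reduction ("dilution
factor") of the sample's contamination:

* Traditional goal: HI <= 1 and CR <= 1 per million, so the factor is
  max(HI, CR, 1) by linearity.
* Bioactivity goal: no more than 10% of the in vitro endpoints
  bioactive; the goal dilution is the 10th percentile of the sample's
  PODs (censored endpoints count in the denominator but are pooled at
  +inf), capped so that the active fraction at the goal is exactly
  <= the threshold; the factor is 1 / goal (baseline = undiluted
  extract), floored at 1.

Residual quantities show how protective each approach is against the
other's target: the active fraction remaining after the traditional
factor, and the HI / CR remaining after the bioactivity factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "RemediationResult", "traditional_factor", "fraction_active",
    "bioactivity_goal", "remediation_table", "dumbbell_table",
]

ACTIVE_THRESHOLD = 0.10
BASELINE_DILUTION = 1.0


@dataclass(frozen=True)
class RemediationResult:
    sample_id: str
    hi: float
    cr: float
    traditional_factor: float
    baseline_fraction_active: float
    bioactivity_goal_dilution: float
    bioactivity_factor: float
    residual_fraction_active_after_traditional: float
    residual_hi_after_bioactivity: float
    residual_cr_after_bioactivity: float


def traditional_factor(hi: float, cr: float) -> float:
    """Fold-reduction achieving HI <= 1 and CR <= 1 per million
    (equality counts as compliant); 1 when already compliant."""
    if hi < 0 or cr < 0:
        raise ConfigurationError("HI and CR must be nonnegative")
    return max(hi, cr, 1.0)


def fraction_active(pods: np.ndarray, censored: np.ndarray,
                    dilution: float) -> float:
    """Fraction of endpoints active at ``dilution``: an endpoint counts
    as active iff it is not censored and dilution >= its POD."""
    if not 0 < dilution <= BASELINE_DILUTION:
        raise ConfigurationError("dilution must be in (0, 1]")
    pods = np.asarray(pods, float)
    censored = np.asarray(censored, bool)
    if pods.size == 0:
        raise InsufficientDataError("no PODs for sample")
    active = (~censored) & (dilution >= pods)
    return float(active.sum()) / pods.size


def bioactivity_goal(pods: np.ndarray, censored: np.ndarray,
                     threshold: float = ACTIVE_THRESHOLD) -> tuple:
    """Goal dilution and fold-reduction for <= ``threshold`` fraction of
    endpoints active.

    The goal is the interpolated (type-7) ``threshold`` quantile of the
    POD pool (censored endpoints at +inf).  Because the interpolated
    quantile can sit above the floor(threshold * m)+1-th order statistic
    — which would leave more than the threshold fraction active under
    the "dilution >= POD" rule — the goal is capped at the largest POD
    value whose active fraction is compliant (or just below the
    smallest POD when none is).  Returns (goal_dilution, factor) with
    factor >= 1.
    """
    pods = np.asarray(pods, float)
    censored = np.asarray(censored, bool)
    if pods.size == 0:
        raise InsufficientDataError("no PODs for sample")
    pool = np.where(censored, np.inf, pods)
    if fraction_active(pods, censored, BASELINE_DILUTION) <= threshold:
        return BASELINE_DILUTION, 1.0
    q = float(np.quantile(pool, threshold))  # type-7 linear interpolation
    goal = min(q, BASELINE_DILUTION)
    if fraction_active(pods, censored, goal) > threshold:
        actives = np.sort(pods[~censored])
        compliant = [p for p in actives
                     if fraction_active(pods, censored, p) <= threshold]
        if compliant:
            goal = float(max(compliant))
        else:
            goal = float(actives[0]) * (1.0 - 1e-12)
    factor = max(1.0, BASELINE_DILUTION / goal)
    return goal, factor


def remediation_table(pods: pd.DataFrame, risk: pd.DataFrame,
                      scenario: str = "residential_soil",
                      threshold: float = ACTIVE_THRESHOLD) -> pd.DataFrame:
    """Per-sample remediation comparison.

    ``pods`` is the long POD table (sample_id, endpoint_id, pod,
    censored); ``risk`` the long risk table (sample_id, scenario, HI,
    CR).  Residuals: fraction active at 1/traditional_factor, and
    HI / CR divided by the bioactivity factor.
    """
    r = risk[risk["scenario"] == scenario].set_index("sample_id")
    rows = []
    for sid, sub in pods.groupby("sample_id", sort=True):
        if sid not in r.index:
            raise ConfigurationError(f"no risk result for sample {sid!r}")
        p = sub["pod"].values
        c = sub["censored"].values.astype(bool)
        hi, cr = float(r.loc[sid, "HI"]), float(r.loc[sid, "CR"])
        tf = traditional_factor(hi, cr)
        goal, bf = bioactivity_goal(p, c, threshold=threshold)
        rows.append(RemediationResult(
            sample_id=sid, hi=hi, cr=cr,
            traditional_factor=tf,
            baseline_fraction_active=fraction_active(p, c, BASELINE_DILUTION),
            bioactivity_goal_dilution=goal,
            bioactivity_factor=bf,
            residual_fraction_active_after_traditional=fraction_active(p, c, 1.0 / tf),
            residual_hi_after_bioactivity=hi / bf,
            residual_cr_after_bioactivity=cr / bf,
        ))
    return pd.DataFrame([vars(x) for x in rows])


def dumbbell_table(remediation: pd.DataFrame,
                   threshold: float = ACTIVE_THRESHOLD) -> pd.DataFrame:
    """Long-format table for dumbbell plots: per sample, baseline versus
    post-remediation values of each metric under the opposite goal."""
    rows = []
    for _, r in remediation.iterrows():
        rows.append({"sample_id": r["sample_id"], "metric": "fraction_active",
                     "baseline": r["baseline_fraction_active"],
                     "after_remediation": r["residual_fraction_active_after_traditional"],
                     "remediation_basis": "traditional",
                     "goal": threshold})
        rows.append({"sample_id": r["sample_id"], "metric": "cancer_risk_per_million",
                     "baseline": r["cr"],
                     "after_remediation": r["residual_cr_after_bioactivity"],
                     "remediation_basis": "bioactivity",
                     "goal": 1.0})
    return pd.DataFrame(rows)
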