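"""Screening-level hazard index and cancer risk for PAHs.

Alkylated homolog concentrations are added to their parent PAHs (a
conservative aggregation), then each sample's hazard index (HI) and
incremental lifetime cancer risk (CR) are computed as sums of
concentration / screening-level ratios:

    HI = sum_i C_i / SL_nc_i(scenario)
    CR = sum_i C_i / SL_ca_i(scenario)   [cases per million]

where SL_nc is the soil/sediment concentration at hazard quotient 1 and
SL_ca the concentration at 1e-6 risk, so the ratio form is algebraically
equivalent to the full intake equations with the exposure assumptions
folded into the screening levels.  Two exposure scenarios are carried:
recreational sediment contact (short, infrequent exposure) and
residential soil (sediment deposited on land).

The packaged screening-level table is ILLUSTRATIVE ONLY — loosely
realistic magnitudes for the 16 priority PAHs — and real assessments
must supply authoritative, current values (e.g. from the EPA RSL
calculator) via ``load_tox_params``.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synth import HOMOLOG_SERIES, PRIORITY_PARENTS, TOTAL_IDS

SCENARIOS = ("recreational_sediment", "residential_soil")

__all__ = ["SCENARIOS", "default_tox_params", "load_tox_params",
           "default_lineage", "aggregate_alkylated", "hazard_index",
           "cancer_risk", "risk_table"]

# Illustrative screening levels, ng/g dry weight.  sl_nc at HQ = 1,
# sl_ca at risk = 1e-6 (NaN = not treated as a carcinogen here).
# Residential-soil values are lower (longer exposure) than recreational.
_SL_CA_RESIDENTIAL = {
    "naphthalene": 8.0e3,
    "benz[a]anthracene": 4.4e3,
    "chrysene": 4.4e5,
    "benzo[b]fluoranthene": 4.4e3,
    "benzo[k]fluoranthene": 4.4e4,
    "benzo[a]pyrene": 4.4e2,
    "indeno[1,2,3-cd]pyrene": 4.4e3,
    "dibenz[a,h]anthracene": 4.4e2,
}
_SL_NC_RESIDENTIAL = {p: 8.0e5 for p in PRIORITY_PARENTS}
_SL_NC_RESIDENTIAL.update({
    "naphthalene": 2.2e5,
    "fluorene": 6.0e5,
    "anthracene": 4.0e6,
    "fluoranthene": 5.6e5,
    "pyrene": 4.4e5,
})
_REC_OVER_RES = 50.0  # recreational exposure ~50x less intensive


def default_tox_params() -> pd.DataFrame:
    """Illustrative ToxParamTable: one row per parent PAH x scenario
    with sl_nc and sl_ca columns (ng/g)."""
    rows = []
    for parent in PRIORITY_PARENTS:
        sl_nc_res = _SL_NC_RESIDENTIAL[parent]
        sl_ca_res = _SL_CA_RESIDENTIAL.get(parent, np.nan)
        rows.append({"analyte_id": parent, "scenario": "residential_soil",
                     "sl_nc": sl_nc_res, "sl_ca": sl_ca_res})
        rows.append({"analyte_id": parent, "scenario": "recreational_sediment",
                     "sl_nc": sl_nc_res * _REC_OVER_RES,
                     "sl_ca": sl_ca_res * _REC_OVER_RES})
    return pd.DataFrame(rows)


def load_tox_params(path: Optional[str] = None) -> pd.DataFrame:
    """Load a screening-level table (CSV with analyte_id, scenario,
    sl_nc, sl_ca); defaults to the illustrative packaged table."""
    if path is None:
        return default_tox_params()
    table = pd.read_csv(path)
    required = {"analyte_id", "scenario", "sl_nc", "sl_ca"}
    if not required.issubset(table.columns):
        raise ConfigurationError(f"tox params must have columns {sorted(required)}")
    if (table["sl_nc"] <= 0).any() or (table["sl_ca"].dropna() <= 0).any():
        raise ConfigurationError("screening levels must be positive")
    return table


def default_lineage(analyte_ids) -> pd.Series:
    """Parent assignment from the panel naming convention: parents map
    to themselves, 'Ck-<parent>' homologs to their parent; totals are
    excluded."""
    lineage = {}
    for aid in analyte_ids:
        if aid in TOTAL_IDS:
            continue
        if aid in PRIORITY_PARENTS:
            lineage[aid] = aid
        elif "-" in aid:
            prefix, parent = aid.split("-", 1)
            if parent in HOMOLOG_SERIES and prefix.startswith("C"):
                lineage[aid] = parent
            else:
                raise ConfigurationError(f"cannot infer parent for analyte {aid!r}")
        else:
            raise ConfigurationError(f"cannot infer parent for analyte {aid!r}")
    return pd.Series(lineage, name="parent")


def aggregate_alkylated(chem: pd.DataFrame,
                        lineage: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Effective parent concentrations: parent + sum of its alkylated
    homologs; total columns are excluded from the summation."""
    if lineage is None:
        lineage = default_lineage(chem.columns)
    lineage = pd.Series(dict(lineage))
    parents = sorted(lineage.unique(), key=list(PRIORITY_PARENTS).index)
    out = pd.DataFrame(0.0, index=chem.index, columns=parents)
    for aid, parent in lineage.items():
        if aid in chem.columns:
            out[parent] = out[parent] + chem[aid]
    return out


def _ratio_sum(parent_conc: pd.DataFrame, params: pd.DataFrame,
               scenario: str, column: str, on_missing: str) -> pd.Series:
    if scenario not in set(params["scenario"]):
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    sl = (params[params["scenario"] == scenario]
          .set_index("analyte_id")[column].dropna())
    missing = [c for c in parent_conc.columns if c not in sl.index]
    if missing and column == "sl_nc":
        if on_missing == "error":
            raise ConfigurationError(f"no {column} for {missing} in {scenario}")
        warnings.warn(f"skipping parents without {column}: {missing}", stacklevel=3)
    cols = [c for c in parent_conc.columns if c in sl.index]
    return (parent_conc[cols] / sl[cols]).sum(axis=1)


def hazard_index(parent_conc: pd.DataFrame, params: pd.DataFrame,
                 scenario: str, on_missing: str = "warn") -> pd.Series:
    """HI = sum of concentration / noncancer screening level."""
    return _ratio_sum(parent_conc, params, scenario, "sl_nc", on_missing).rename("HI")


def cancer_risk(parent_conc: pd.DataFrame, params: pd.DataFrame,
                scenario: str, on_missing: str = "warn") -> pd.Series:
    """CR in cases per million = sum of concentration / cancer
    screening level (SL at 1e-6 risk)."""
    return _ratio_sum(parent_conc, params, scenario, "sl_ca", on_missing).rename("CR")


def risk_table(chem: pd.DataFrame, params: Optional[pd.DataFrame] = None,
               scenarios=SCENARIOS,
               lineage: Optional[Mapping[str, str]] = None) -> pd.DataFrame:
    """Per-sample HI and CR under each scenario (long format)."""
    if params is None:
        params = default_tox_params()
    parent_conc = aggregate_alkylated(chem, lineage=lineage)
    frames = []
    for scenario in scenarios:
        hi = hazard_index(parent_conc, params, scenario)
        cr = cancer_risk(parent_conc, params, scenario)
        frames.append(pd.DataFrame({
            "sample_id": parent_conc.index, "scenario": scenario,
            "HI": hi.values, "CR": cr.values,
        }))
    return pd.concat(frames, ignore_index=True)
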