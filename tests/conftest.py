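import numpy as np
import pandas as pd
import pytest

from sedscreen import default_design, generate_study


@pytest.fixture(scope="session")
def design():
    return default_design()


@pytest.fixture(scope="session")
def study(design):
    """One default synthetic study shared across read-only tests."""
    return generate_study(design, seed=7)


def true_pods_table(truth, design) -> pd.DataFrame:
    """Long POD table built from the generator's analytic ground truth
    (inactive endpoints censored at the maximum tested dilution)."""
    tp = truth.true_pod
    long = tp.stack(future_stack=True).rename("pod").reset_index()
    long.columns = ["sample_id", "endpoint_id", "pod"]
    long["censored"] = long["pod"].isna()
    long["pod"] = long["pod"].fillna(float(design.dilution_ladder[0]))
    cell = {e.endpoint_id: e.cell_type for e in design.endpoints}
    long["cell_type"] = long["endpoint_id"].map(cell)
    return long


def rng_for(name: str) -> np.random.Generator:
    """Deterministic per-test RNG."""
    return np.random.default_rng(abs(hash(name)) % (2**31))
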