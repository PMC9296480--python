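import numpy as np
import pandas as pd
import pytest

from relabund.synthetic_data import make_fixture
from relabund.model_fitting import prepare_design


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small B-P scenario, prepared once for fitting-layer tests."""
    fx = make_fixture("well_identified_bp", seed=42)
    bundle = prepare_design(fx["checklists"], fx["sites"])
    return fx, bundle


@pytest.fixture()
def toy_sites():
    """Four sites with hand-set land-cover fractions and elevation."""
    return pd.DataFrame(
        {
            "site_id": ["a", "b", "c", "d"],
            "x": [25.0, 75.0, 125.0, 175.0],
            "y": [25.0, 25.0, 25.0, 25.0],
            "elevation": [100.0, 200.0, 150.0, 50.0],
            "pct_water": [0.1, 0.2, 0.3, 0.4],
            "pct_trees": [0.2, 0.4, 0.6, 0.9],
            "pct_agriculture": [0.3, 0.1, 0.05, 0.2],
            "pct_other_vegetation": [0.2, 0.1, 0.02, 0.3],
        }
    )


@pytest.fixture()
def toy_checklists():
    rng = np.random.default_rng(7)
    rows = []
    for i, sid in enumerate(["a", "b", "c", "d"]):
        for j in range(3):
            rows.append(
                {
                    "checklist_id": f"C{i}{j}",
                    "site_id": sid,
                    "x": 25.0 + 50.0 * i,
                    "y": 25.0,
                    "count": int(rng.poisson(2)),
                    "duration_minutes": float(rng.uniform(10, 120)),
                    "n_observers": int(rng.integers(1, 4)),
                    "time_of_day": float(rng.uniform(6, 18)),
                    "julian_date": int(rng.integers(100, 170)),
                    "protocol": "stationary",
                    "complete": True,
                }
            )
    return pd.DataFrame(rows)
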