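import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import tmtquant as tq

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def design() -> pd.DataFrame:
    return tq.make_study_design()


@pytest.fixture(scope="session")
def small_study(design):
    """A small but fully realistic simulated study (default conditions)."""
    cfg = tq.SimulationConfig(n_proteins=40, seed=7)
    db, _, truth, psms = tq.simulate_study(cfg, design=design)
    return cfg, db, truth, psms


def make_psm_frame(rows: list[dict]) -> pd.DataFrame:
    """PSM DataFrame from partial row dicts; unspecified reporters = 100."""
    out = []
    for row in rows:
        full = {"sequence": "PEPTIDEK", "protein": "P1", "interference": 0.0}
        full.update({c: 100.0 for c in tq.REPORTER_COLUMNS})
        full.update(row)
        out.append(full)
    return pd.DataFrame(out, columns=["sequence", "protein", "interference", *tq.REPORTER_COLUMNS])


@pytest.fixture()
def psm_frame_factory():
    return make_psm_frame
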