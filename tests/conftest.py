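import numpy as np
import pandas as pd
import pytest

import mcds


@pytest.fixture(scope="session")
def small_bundle():
    """One small synthetic cohort reused across read-only tests."""
    params = mcds.SimulationParams(n_patients=4000, seed=42)
    return mcds.simulate_cohort(params)


@pytest.fixture()
def tiny_claims(tmp_path):
    """Three valid prescription rows on disk."""
    path = tmp_path / "claims.csv"
    path.write_text(
        "patient_id,atc_code,dispense_date,n_packages\n"
        "p1,A10BA02,2016-03-01,1\n"
        "p1,A10BA02,2016-09-15,2\n"
        "p2,N06DA02,2017-11-15,1\n"
    )
    return path


@pytest.fixture()
def tiny_cohort(tmp_path):
    path = tmp_path / "cohort.csv"
    path.write_text(
        "patient_id,age_at_index,sex,index_date\n"
        "p1,70,female,2018-01-01\n"
        "p2,81,male,2018-01-01\n"
        "p3,55,female,2018-01-01\n"
    )
    return path


@pytest.fixture()
def tiny_outcomes(tmp_path):
    path = tmp_path / "outcomes.csv"
    path.write_text(
        "patient_id,death_date,hospitalization_date\n"
        "p1,2018-04-11,\n"
        "p2,,2018-06-01\n"
        "p3,,\n"
    )
    return path


def survival_frame(times, events):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(times))],
        "time": np.asarray(times, dtype=int),
        "event": np.asarray(events, dtype=int),
    })
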