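import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_cohort_frame():
    """One modest simulated cohort reused by read-only tests."""
    from candgene.synthetic_cohort import (
        CohortSpec, cohort_to_frame, simulate_cohort,
    )

    spec = CohortSpec(n_cases=400, n_controls=400, seed=20240)
    return cohort_to_frame(simulate_cohort(spec))


@pytest.fixture(scope="session")
def regression_design(small_cohort_frame):
    """Analysis-scale design matrix (dosages + transformed covariates)."""
    df = small_cohort_frame
    X = pd.DataFrame({
        "rs738409": df["rs738409"].astype(float),
        "rs58542926": df["rs58542926"].astype(float),
        "rs1260326": df["rs1260326"].astype(float),
        "rs641738": df["rs641738"].astype(float),
        "age": df["age"],
        "sex_m": (df["sex"] == "M").astype(float),
        "bmi": df["bmi"],
        "log_homa": np.log(df["homa_ir"]),
        "log_tg": np.log(df["tg"]),
    })
    y = (df["status"] == "case").astype(int).to_numpy()
    return X, y
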