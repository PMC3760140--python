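import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small mixed-strategy cohort shared by pipeline-level tests."""
    import twostep as ts

    pop = ts.PopulationSpec(
        n_subjects=24,
        subsample_sizes=(12, 12),
        subsample_trials=(120, 100),
        miss_rate=0.014,
    )
    trials, covariates, truth = ts.simulate_population(
        pop, ts.TaskConfig(), np.random.default_rng(2024)
    )
    return trials, covariates, truth


@pytest.fixture(scope="session")
def null_rows():
    """Design rows for subjects whose stays ignore the predictors."""
    import twostep as ts

    spec = ts.RegressionGenSpec(
        fixed_coefs={"Intercept": 0.3},
        re_cov=tuple(map(tuple, (0.0 * np.eye(4)).tolist())),
        n_subjects=60,
        n_trials=120,
    )
    return ts.simulate_from_regression(spec, np.random.default_rng(31))


def make_trials(records: list[dict]) -> pd.DataFrame:
    """Hand-build a trial table from sparse dicts (missing fields -> NA)."""
    from twostep.task import TRIAL_COLUMNS

    rows = []
    for rec in records:
        row = {
            "subject_id": rec.get("subject_id", "s001"),
            "trial": rec["trial"],
            "choice1": rec.get("choice1", pd.NA),
            "pair": rec.get("pair", pd.NA),
            "common": rec.get("common", pd.NA),
            "choice2": rec.get("choice2", pd.NA),
            "reward": rec.get("reward", pd.NA),
            "missed": rec.get("missed", False),
        }
        rows.append(row)
    df = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return df.astype(
        {
            "trial": "int64",
            "choice1": "Int64",
            "pair": "Int64",
            "common": "boolean",
            "choice2": "Int64",
            "reward": "Int64",
            "missed": "bool",
        }
    )
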