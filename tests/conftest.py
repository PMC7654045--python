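"""Shared fixtures: small hand-written record sets and simulated cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import seasonmort as sm
from seasonmort import cohort_data

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: One fixed seed for every stochastic fixture in the suite.
SEED = 20240917


def make_records(rows) -> pd.DataFrame:
    """Build a person-level frame from (birth, death, sex) string triples."""
    df = pd.DataFrame(rows, columns=["birth_date", "death_date", "sex"])
    df["birth_date"] = pd.to_datetime(df["birth_date"])
    df["death_date"] = pd.to_datetime(df["death_date"])
    return df


@pytest.fixture(scope="session")
def recovery_truth() -> sm.HazardParams:
    """Generating parameters for the large parameter-recovery cohort."""
    return sm.HazardParams(mu=6e-5, beta=2.4e-4, a1=0.2, a2=0.25)


@pytest.fixture(scope="session")
def recovery_cohort(recovery_truth):
    """One simulated 100,000-person cohort plus its daily counts and fit."""
    rng = np.random.default_rng(SEED)
    df = sm.simulate_cohort(recovery_truth, 1830, "male", 100_000, rng)
    cohort = cohort_data.build_cohort(df, 1830, "male")
    counts = cohort_data.build_daily_counts(cohort)
    fit = sm.fit_poisson(counts)
    return {"truth": recovery_truth, "cohort": cohort, "counts": counts, "fit": fit}


@pytest.fixture(scope="session")
def small_study():
    """A 4-cohort synthetic study small enough for pipeline round trips."""
    config = sm.ScenarioConfig(
        birth_years=[1820, 1880],
        sexes=("male", "female"),
        cohort_size=3_000,
        seed=SEED,
        trajectories={
            sex: {
                "mu_star": (5.0e-5, 4.2e-5),
                "beta_per_year": (0.088, 0.088),
                "h": (1.9, 1.2),
                "peak_day": (41.0, 55.0),
            }
            for sex in ("male", "female")
        },
    )
    return config, sm.generate_study(config)
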