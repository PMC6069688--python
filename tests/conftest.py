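import numpy as np
import pandas as pd
import pytest

from peann.survdata import (
    Covariate,
    SurvivalCohort,
    build_interval_grid,
    expand_person_period,
)


def make_cohort(times, events, covs=None, schema=None, treatment=None):
    """Build a small cohort from parallel arrays (helper for tests)."""
    n = len(times)
    df = pd.DataFrame(
        {"subject_id": np.arange(n), "time": times, "event": events}
    )
    covs = covs or {}
    for name, vals in covs.items():
        df[name] = vals
    if schema is None:
        schema = tuple(
            Covariate(name, "categorical", tuple(sorted(set(map(str, vals)))))
            for name, vals in covs.items()
        )
    return SurvivalCohort(df, schema, treatment)


@pytest.fixture
def grid72():
    return build_interval_grid(3.0, 72.0)


@pytest.fixture
def toy_cohort():
    """Nine subjects, binary treatment, mixed events/censoring."""
    rng = np.random.default_rng(42)
    times = rng.exponential(20.0, 9).round(2) + 0.5
    events = np.array([1, 0, 1, 1, 0, 1, 0, 1, 1])
    treat = ["control", "active"] * 4 + ["control"]
    return make_cohort(
        times,
        events,
        {"treatment": treat},
        schema=(Covariate("treatment", "categorical", ("control", "active")),),
        treatment="treatment",
    )


@pytest.fixture
def toy_pp(toy_cohort, grid72):
    return expand_person_period(toy_cohort, grid72)
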