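import numpy as np
import pandas as pd
import pytest

from psycop import simulate
from psycop.datatypes import BehaviorTable, EventStream


@pytest.fixture(scope="session")
def cohort():
    """Default 64-animal synthetic cohort (15/17/15/17) with missing cells."""
    table, truth = simulate.simulate_cohort(simulate.CohortSpec(), seed=7)
    return table, truth


@pytest.fixture(scope="session")
def complete_cohort():
    """Cohort with no missing cells (all default effects planted)."""
    spec = simulate.CohortSpec(missing_prob=0.0)
    table, truth = simulate.simulate_cohort(spec, seed=11)
    return table, truth


def null_spec(n_variables=5, n_per_group=12, missing_prob=0.0):
    eff = pd.DataFrame(
        0.0, index=[f"v{i + 1}" for i in range(n_variables)], columns=["G", "E", "GxE"]
    )
    return simulate.CohortSpec(
        group_sizes=(n_per_group,) * 4, effects=eff, missing_prob=missing_prob
    )


@pytest.fixture()
def tiny_table():
    """Hand-built 8-animal table with one missing cell."""
    idx = pd.Index([f"m{i}" for i in range(8)], name="animal_id")
    data = pd.DataFrame(
        {
            "a": [1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0, 8.0],
            "b": [2.0, 1.0, 0.5, 0.25, 3.0, 2.5, 1.5, 0.75],
        },
        index=idx,
    )
    factors = pd.DataFrame(
        {
            "genotype": ["wt", "wt", "wt", "wt", "tg", "tg", "tg", "tg"],
            "environment": ["ns", "ns", "sd", "sd", "ns", "ns", "sd", "sd"],
        },
        index=idx,
    )
    return BehaviorTable(data=data, factors=factors)


def build_stream(rows) -> EventStream:
    """EventStream from (animal, iso_time, corner, side, kind, duration) tuples."""
    df = pd.DataFrame(
        rows, columns=["animal_id", "timestamp", "corner", "side", "kind", "duration"]
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return EventStream(df)
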