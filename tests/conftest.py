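import numpy as np
import pandas as pd
import pytest

from flocknet.groups import GatheringEvent, GroupByIndividualMatrix, build_group_matrix


def make_matrix(group_specs):
    """Build a GroupByIndividualMatrix from (members, feeder, period, day, time) tuples."""
    gatherings = []
    for i, (members, feeder, period, day, time_s) in enumerate(group_specs, start=1):
        gatherings.append(
            GatheringEvent(
                group_id=f"G{i:04d}",
                feeder_id=feeder,
                day=day,
                sampling_period=period,
                centre_time_s=float(time_s),
                spread_s=0.0,
                members=frozenset(members),
            )
        )
    return build_group_matrix(gatherings)


def random_matrix(rng, n_groups=50, n_individuals=20, n_feeders=3, n_periods=2, mean_size=4):
    """Random group matrix with (feeder, period) strata and increasing times."""
    ids = [f"i{j:02d}" for j in range(n_individuals)]
    specs = []
    for g in range(n_groups):
        size = max(1, min(n_individuals, rng.poisson(mean_size)))
        members = rng.choice(ids, size=size, replace=False)
        feeder = f"F{rng.integers(n_feeders)}"
        period = int(rng.integers(1, n_periods + 1))
        day = 2 * period - 1 + int(rng.integers(2))
        t = float(rng.uniform(0, 36000))
        specs.append((members, feeder, period, day, t))
    return make_matrix(specs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_phenotypes():
    return pd.DataFrame(
        {
            "individual_id": [f"i{j:02d}" for j in range(20)],
            "sex": ["male", "female"] * 10,
            "age_class": ["adult"] * 12 + ["juvenile"] * 8,
            "residency": ["local"] * 14 + ["immigrant"] * 6,
            "wing_mm": np.linspace(70, 80, 20),
            "tarsus_mm": np.linspace(19, 21, 20),
        }
    )
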