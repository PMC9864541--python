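import numpy as np
import pytest

from imputebench import MixedDataset, fixture_brfss_like, generate_population
from imputebench.schema import VariableSchema


def subset_dataset(pop: MixedDataset, names: list[str]) -> MixedDataset:
    """Column-subset of a dataset, keeping the schema entries in order."""
    sch = [v for v in pop.schema if v.name in names]
    return MixedDataset(pop.data[[v.name for v in sch]], sch)


@pytest.fixture(scope="session")
def brfss_pop():
    """One mid-size draw of the diabetes-module fixture, shared read-only."""
    return generate_population(fixture_brfss_like(seed=17, n=4000))


@pytest.fixture(scope="session")
def small_pop(brfss_pop):
    """Compact 3-covariate + 1-continuous-outcome view for fast method tests."""
    return subset_dataset(brfss_pop, ["age_group", "bmi", "general_health", "age_diagnosed"])


def make_continuous_schema(names, roles=None):
    roles = roles or ["covariate"] * (len(names) - 1) + ["outcome"]
    return tuple(VariableSchema(n, r, "continuous") for n, r in zip(names, roles))
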