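import numpy as np
import pytest

from pgxbeacon import TransportPolicy
from pgxbeacon.mock import CohortSpec, generate_cohort, serve_mock

FAST_POLICY = TransportPolicy(timeout=5.0, retries=0, backoff=0.0)


@pytest.fixture(scope="session")
def dataset():
    """A small deterministic cohort shared by client/server tests."""
    return generate_cohort(CohortSpec(n_individuals=30, seed=11))


@pytest.fixture(scope="session")
def server(dataset):
    srv = serve_mock(dataset)
    yield srv
    srv.stop()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_survival_records(rng, n=40, groups=("g1", "g2"), hazard=0.05):
    """Exponential event times with uniform censoring; used across modules."""
    from pgxbeacon import SurvivalRecord

    records = []
    for g in groups:
        times = rng.exponential(1.0 / hazard, n)
        censor = rng.uniform(0, 2.0 / hazard, n)
        for i in range(n):
            t = min(times[i], censor[i])
            records.append(
                SurvivalRecord(f"{g}-{i}", float(t), bool(times[i] <= censor[i]), g)
            )
    return records
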