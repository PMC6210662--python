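import numpy as np
import pytest

from mtshazard import (
    GhsRecord,
    HazardCategory,
    SimulationConfig,
    VARIABLES,
    generate,
    quantify_all,
)

C = HazardCategory


def make_record(cas="0-00-0", name="x", **overrides) -> GhsRecord:
    """A record of all Not Classified with named endpoint overrides."""
    endpoints = {v: C.NOT_CLASSIFIED for v in VARIABLES}
    endpoints.update(overrides)
    return GhsRecord(cas=cas, name=name, endpoints=endpoints)


@pytest.fixture(scope="session")
def small_population():
    """A 400-chemical synthetic table with 10 planted hazards (fixed seed)."""
    cfg = SimulationConfig(n_chemicals=400, n_planted_hazards=10, seed=20260927)
    records, truth = generate(cfg)
    return records, truth


@pytest.fixture(scope="session")
def small_scores(small_population):
    records, _ = small_population
    return quantify_all(records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
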