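import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from trialcea import costing, synth
from trialcea.utility import SF12Mapping, TariffTable

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def unit_costs() -> costing.UnitCostTable:
    return costing.load_unit_costs()


@pytest.fixture(scope="session")
def small_trial() -> pd.DataFrame:
    """Default-design synthetic trial, complete follow-up, fixed seed."""
    return synth.generate_trial(synth.TrialDesign(seed=11))


@pytest.fixture(scope="session")
def toy_tariff() -> TariffTable:
    """Synthetic two-dimension tariff used to exercise the scoring rules."""
    return TariffTable(
        decrements={
            ("pain", 1): 0.0,
            ("pain", 2): -0.1,
            ("pain", 3): -0.3,
            ("mental_health", 1): 0.0,
            ("mental_health", 2): -0.2,
        },
        intercept=1.0,
        most_severe=-0.05,
        floor=0.345,
    )


@pytest.fixture(scope="session")
def toy_mapping() -> SF12Mapping:
    """Synthetic item->dimension rule table: two dimensions, one item each."""
    rules = {
        "pain": [(3, "i8", frozenset({5})), (2, "i8", frozenset({3, 4}))],
        "mental_health": [(2, "i6", frozenset({4, 5}))],
    }
    return SF12Mapping(rules=rules, item_levels={"i8": 5, "i6": 5})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
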