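import numpy as np
import pytest

from premio import (
    SynthConfig,
    canonical_objectives,
    default_fee_schedule,
    generate_alternatives,
    published_preferences,
    scenario_dataset,
)


@pytest.fixture(scope="session")
def specs():
    return canonical_objectives()


@pytest.fixture(scope="session")
def scenario():
    return scenario_dataset()


@pytest.fixture(scope="session")
def prefs_pair():
    return published_preferences()


@pytest.fixture(scope="session")
def fees():
    return default_fee_schedule()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture()
def synth31():
    return generate_alternatives(SynthConfig(n=31, seed=7))


def random_alternative_set(rng, n, specs):
    """Random alternative set on the canonical five objectives."""
    from premio import AlternativeSet, TherapyRecord

    records = []
    for i in range(n):
        records.append(
            TherapyRecord(
                id=f"r{i:04d}",
                study=f"study {i}",
                exercise_type="mixed",
                objectives={
                    "cost_eur": float(rng.uniform(0, 1500)),
                    "pain_net_change_pct": float(rng.uniform(-5, 45)),
                    "function_net_change_pct": float(rng.uniform(-5, 45)),
                    "supervised_sessions": float(rng.integers(0, 37)),
                    "period_weeks": float(rng.integers(8, 49)),
                },
            )
        )
    return AlternativeSet(specs, records)
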