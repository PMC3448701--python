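import numpy as np
import pytest
from hypothesis import settings

import scor

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_surv():
    """Eight patients with two censored, distinct event times."""
    return scor.SurvivalData(
        [f"s{i}" for i in range(8)],
        [2, 4, 5, 7, 9, 12, 14, 20],
        [1, 1, 0, 1, 1, 0, 1, 1],
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """n=200 cohort: one 40-gene poor-prognosis module over 300 null genes."""
    return scor.simulate_cohort(
        scor.SimConfig(
            n_samples=200,
            n_null_genes=300,
            modules=[scor.ModuleSpec(40, 0.8, "poor", 0.7)],
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def planted_result(planted_cohort):
    return scor.run_scor(
        planted_cohort.expression,
        planted_cohort.survival,
        scor.ScorConfig(rounds=60, rng_seed=7),
    )


@pytest.fixture(scope="session")
def two_block_cohort():
    """Two opposite-direction correlated modules over a null background."""
    return scor.simulate_cohort(
        scor.SimConfig(
            n_samples=200,
            n_null_genes=200,
            modules=[
                scor.ModuleSpec(30, 0.85, "poor", 0.8),
                scor.ModuleSpec(30, 0.85, "good", 0.8),
            ],
            seed=21,
        )
    )
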