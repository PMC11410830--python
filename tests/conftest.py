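import numpy as np
import pandas as pd
import pytest

from gcfpool import (
    DEFAULT_FACTORS,
    FactorPool,
    make_ground_truth,
    sample_design,
    simulate_experiment,
)


@pytest.fixture(scope="session")
def pool() -> FactorPool:
    return FactorPool(DEFAULT_FACTORS)


@pytest.fixture(scope="session")
def small_pool() -> FactorPool:
    return FactorPool(("a", "b", "c", "d"))


@pytest.fixture(scope="session")
def noiseless_additive(pool):
    """A small noise-free additive-world experiment with known truth."""
    truth = make_ground_truth(
        {"control_mean": 10.0, "control_sd": 0.0, "world": "additive"}, seed=5
    )
    design = sample_design(
        pool,
        levels=(2, 5),
        n_per_level=4,
        replicate_plan={"control": 5, "water_control": 2, "single": 3, "multi": 2},
        seed=5,
    )
    responses = simulate_experiment(truth, design, seed=5)
    return truth, design, responses


@pytest.fixture(scope="session")
def noisy_small(pool):
    """A small sigma=1 additive-world experiment (for smoke/shape tests)."""
    truth = make_ground_truth({"control_sd": 1.0, "world": "additive"}, seed=9)
    design = sample_design(
        pool,
        levels=(2, 5),
        n_per_level=4,
        replicate_plan={"control": 8, "water_control": 2, "single": 4, "multi": 2},
        seed=9,
    )
    responses = simulate_experiment(truth, design, seed=9)
    return truth, design, responses
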