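import numpy as np
import pytest

from itc_uq import (
    HeatCurve,
    SimulationDesign,
    ThermoParams,
    default_schedule,
    simulate_dataset,
    true_heats,
)

REFERENCE_TRUTH = dict(dG=-10.0, dH=-5.0, dH0=0.5e-6, R0=0.1, Ls=1.0, sigma=1e-6)


@pytest.fixture(scope="session")
def schedule():
    return default_schedule()


@pytest.fixture(scope="session")
def truth(schedule):
    return ThermoParams(**REFERENCE_TRUTH)


@pytest.fixture(scope="session")
def noiseless_curve(schedule, truth):
    """A 24-injection curve at the reference truth with zero noise."""
    return HeatCurve(
        heats=true_heats(truth, schedule),
        schedule=schedule,
        stated_R0=truth.R0,
        stated_Ls=truth.Ls,
        label="noiseless",
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Ten simulated curves at the reference design (10% concentration CV)."""
    return simulate_dataset(SimulationDesign(n_curves=10, seed=7))
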