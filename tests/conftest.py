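import numpy as np
import pytest

from transgroup import stimset
from transgroup.contours import FourierComponent, RadialFrequencyContour
from transgroup.simulate import SimulationConfig, simulate_experiment


def circle(radius: float = 1.0) -> RadialFrequencyContour:
    """A circle expressed as a zero-amplitude RFP contour."""
    return RadialFrequencyContour(
        components=(FourierComponent(2, 0.0, 0.0),), base_radius=radius
    )


def single_component(freq: int, amp: float, phase: float) -> RadialFrequencyContour:
    return RadialFrequencyContour(
        components=(FourierComponent(freq, amp, phase),), base_radius=1.0
    )


@pytest.fixture(scope="session")
def batch8():
    """Eight complete stimulus sets with stratified targets (shared, read-only)."""
    return stimset.generate_batch(8, rng_seed=1234)


@pytest.fixture(scope="session")
def one_set(batch8):
    return batch8[0]


@pytest.fixture(scope="session")
def sim_trials():
    """One simulated experiment under the default configuration."""
    return simulate_experiment(SimulationConfig(), seed=2024)
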