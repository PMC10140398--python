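import numpy as np
import pytest

from somnoseq.simulate import (
    StageSignalSpec,
    calibrate_transition_model,
    derive_seed,
    simulate_hypnogram,
)
from somnoseq.stages import Hypnogram

#: Uniform master seed for all test randomness.
SEED = 0


@pytest.fixture(scope="session")
def default_transition_model():
    return calibrate_transition_model()


@pytest.fixture(scope="session")
def default_signal_spec():
    return StageSignalSpec()


@pytest.fixture(scope="session")
def long_hypnogram(default_transition_model):
    """100k-epoch reference hypnogram from the calibrated chain.

    The seed comes from the package's own derivation scheme, as in
    :func:`somnoseq.simulate.generate_cohort`.
    """
    return simulate_hypnogram(100_000, default_transition_model,
                              seed=derive_seed(SEED, 0))


def random_hypnogram_pair(rng: np.random.Generator, n: int,
                          n_classes: int = 5) -> tuple[Hypnogram, Hypnogram]:
    a = rng.integers(0, n_classes, n)
    b = rng.integers(0, n_classes, n)
    return Hypnogram(a, "a"), Hypnogram(b, "b")
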