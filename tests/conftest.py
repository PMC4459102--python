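import numpy as np
import pytest

from megalomito.simulate import (DamageModel, FragmentationModel,
                                 simulate_reference)


@pytest.fixture(scope="session")
def small_ref():
    """1 kb circular reference used across mapping/consensus tests."""
    return simulate_reference(1000, 0.4, seed=42)


@pytest.fixture(scope="session")
def mito_ref():
    """Full-size 16.5 kb circular reference."""
    return simulate_reference(16500, 0.4, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def hohlenstein_damage():
    """Double-strand damage model with 27% expected terminal C->T."""
    return DamageModel.for_terminal_rate(0.27)


@pytest.fixture()
def short_frags():
    return FragmentationModel(mean_length=60.0, coverage_target=30.0)
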