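import numpy as np
import pytest

from fasdiet import synth
from fasdiet.signatures import FABinSet, SignatureLibrary


@pytest.fixture(scope="session")
def fixture_models():
    return synth.fixture_models()


@pytest.fixture(scope="session")
def models_by_column(fixture_models):
    return {m.column: m for m in fixture_models}


@pytest.fixture(scope="session")
def bin_set(fixture_models):
    return fixture_models[0].bin_set


@pytest.fixture
def two_bin_set():
    return FABinSet(("16:0", "18:1"))


@pytest.fixture
def tiny_library(two_bin_set):
    mat = np.array([[0.2, 0.8], [0.4, 0.6], [0.6, 0.4]])
    return SignatureLibrary.from_arrays(
        mat, two_bin_set, sample_ids=["a", "b", "c"], group="fish"
    )


@pytest.fixture(scope="session")
def prey_library():
    """One simulated prey library at the study's sample sizes."""
    return synth.simulate_prey_library(seed=11)


@pytest.fixture(scope="session")
def prey_taxa():
    return ("fish", "mollusc", "frog", "crayfish")
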