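import numpy as np
import pytest

from ergdecomp import CohortDesign, ComponentParams, decompose_recording, simulate_cohort


@pytest.fixture(scope="session")
def noiseless_params():
    return ComponentParams(noise_sd_uv=0.0)


@pytest.fixture(scope="session")
def noiseless_pair(noiseless_params):
    """One noiseless simulated subject (NT + OHT eye) with its ground truth."""
    design = CohortDesign(
        n_pairs=1, base=noiseless_params, inter_animal_cv=0.0, seed=42
    )
    recordings, truth = simulate_cohort(design)
    return recordings, truth


@pytest.fixture(scope="session")
def noiseless_metrics(noiseless_pair):
    recordings, truth = noiseless_pair
    return decompose_recording(recordings[0]), truth.iloc[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
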