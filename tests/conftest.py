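import numpy as np
import pytest

import kinbayes as kb


@pytest.fixture(scope="session")
def decay2_model():
    return kb.make_exemplar_network("decay2")


@pytest.fixture(scope="session")
def decay2_prior():
    return kb.exemplar_prior("decay2")


@pytest.fixture(scope="session")
def decay2_truth():
    return kb.EXEMPLAR_BETA_TRUE["decay2"]


@pytest.fixture(scope="session")
def pool3_model():
    return kb.make_exemplar_network("pool3_mini")


@pytest.fixture(scope="session")
def decay2_data(decay2_model, decay2_truth):
    """One simulated decay2 dataset at the study defaults (m=3, T=6)."""
    return kb.simulate_dataset(
        decay2_model, decay2_truth, kb.NoiseSpec(), kb.DEFAULT_TIMES, m=3, seed=101
    )


@pytest.fixture
def small_config():
    """A deliberately short sampler configuration for plumbing tests."""
    return kb.SamplerConfig(n_iter=150, burn_in=50, l0=40, dr_onset=60, seed=7)


def make_dataset(times, abundances, isotopomers):
    return kb.TimeSeriesDataset(
        times=np.asarray(times, float),
        abundances=np.asarray(abundances, float),
        isotopomers=list(isotopomers),
    )
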