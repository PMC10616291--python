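import numpy as np
import pytest

from m6adose import synthetic as syn


@pytest.fixture(scope="session")
def default_dose_response():
    """Dose-response table of the default synthetic study (seed 0)."""
    return syn.simulate_dose_response(syn.DEFAULT_DESIGN, seed=0)


@pytest.fixture(scope="session")
def small_array_study():
    """Small noiseless array study with one planted consistent-hyper gene."""
    design = syn.StudyDesign(doses=(6.5,), timepoints=(1.0, 3.0, 7.0), replicates_per_group=3)
    planted = {"g00003": syn.PlantedEffect("consistent-hyper", 4.0)}
    arr, samp, truth = syn.simulate_epiarray(
        design, n_genes=30, planted=planted, noise_sd_log2=0.0, seed=11
    )
    return arr, samp, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
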