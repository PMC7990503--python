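import warnings

import numpy as np
import pytest

from moralcost import hba, synth

warnings.filterwarnings("ignore", category=FutureWarning)

#: fast MCMC settings for unit-test fits (not the acceptance preset)
FAST_MCMC = {"chains": 2, "warmup": 400, "iterations": 300, "seed": 7}


@pytest.fixture(scope="session")
def small_study():
    """8-subject synthetic study from the winning model."""
    data, params = synth.generate_choice_study(
        synth.PopulationSpec(n_subjects=8), seed=101
    )
    return data, params


@pytest.fixture(scope="session")
def small_fit(small_study):
    """Winning-model fit of the small study with fast MCMC settings."""
    data, _ = small_study
    return hba.fit_model(data, 5, FAST_MCMC)


@pytest.fixture(scope="session")
def planted_patterns():
    """Strongly separable pattern pair with planted behavior coupling."""
    pop = synth.draw_population(synth.PopulationSpec(n_subjects=16, seed=5))
    spec = synth.PatternSpec(
        n_subjects=16,
        n_voxels=50,
        condition_effect=3.0,
        shared_signal=1.0,
        behavior_coupling=1.5,
        noise_sd=0.5,
        seed=6,
    )
    pat_a, pat_b, truth = synth.generate_patterns(spec, pop)
    return pat_a, pat_b, truth, pop


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
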