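"""Shared fixtures: synthetic studies and fitted models.

The expensive global fits are session-scoped so that unit tests and the
acceptance suite share them.  Study sizes are desk-scale (see
docs/methods.md): 5 tiles x 10 positions, 10 backgrounds per tile for the
noisy recovery study; smaller for the noiseless exactness checks.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

from allomap.fitting import crossvalidate, fit

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")
from allomap.synth import GeneratorConfig, generate_structure, generate_study


@pytest.fixture(scope="session")
def noiseless_study():
    cfg = GeneratorConfig(
        n_positions=20, n_tiles=2, backgrounds_per_tile=6, noiseless=True
    )
    return generate_study(cfg, seed=1)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_study):
    return fit(noiseless_study.observations, n_states=3)


@pytest.fixture(scope="session")
def noisy_study():
    # the emulated study conditions: 5 tiles, 10 genetic backgrounds per
    # tile, noise sd = 10% of the fitness range of each experiment
    cfg = GeneratorConfig(n_positions=50, n_tiles=5, backgrounds_per_tile=10)
    return generate_study(cfg, seed=7)


@pytest.fixture(scope="session")
def noisy_fit(noisy_study):
    return fit(noisy_study.observations, n_states=3)


@pytest.fixture(scope="session")
def noisy_cv(noisy_study):
    """10-fold CV of the 2-, 3- and 4-state models on the same study."""
    return {
        n: crossvalidate(noisy_study.observations, n_states=n, k_folds=10, seed=3)
        for n in (3, 2, 4)
    }


@pytest.fixture(scope="session")
def structure100():
    structure, active_site = generate_structure(100, seed=5)
    return structure, active_site


def truth_arrays(truth, model):
    """Aligned (true, fitted) arrays for both energies."""
    muts = sorted(model.ddGf, key=str)
    tf = np.array([truth.ddGf[m] for m in muts])
    ff = np.array([model.ddGf[m] for m in muts])
    ta = np.array([truth.ddGa[m] for m in muts])
    fa = np.array([model.ddGa[m] for m in muts])
    return tf, ff, ta, fa
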