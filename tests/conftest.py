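"""Shared fixtures: the synthetic study at a fixed seed, trained once per session.

The expensive fixtures (the two full best-of-100 × 20-repetition ensembles)
are session-scoped; everything downstream (clamping, reclassification,
fabric challenge, acceptance checks) reuses them.
"""

import numpy as np
import pytest

from flychrome import (
    GeneratorConfig,
    SpectrumTable,
    TaskSpec,
    TrainConfig,
    build_excitation_dataset,
    run_ensemble,
)
from flychrome.cli_reports import RunConfig, _derive_seeds, build_study_inputs

#: the fixed master seed defining the study conditions used by the test suite
STUDY_SEED = 0


@pytest.fixture(scope="session")
def study_inputs():
    """Leaves, animals, fabrics, illuminants and receptor templates (seed 0)."""
    return build_study_inputs(RunConfig(master_seed=STUDY_SEED))


@pytest.fixture(scope="session")
def natural_table(study_inputs):
    leaves, animals, _, _, _ = study_inputs
    return SpectrumTable.concat([leaves, animals])


@pytest.fixture(scope="session")
def dataset(study_inputs, natural_table):
    """The 288-record natural excitation database (ln transform)."""
    _, _, _, illuminants, receptors = study_inputs
    return build_excitation_dataset(natural_table, illuminants, receptors)


@pytest.fixture(scope="session")
def fabric_dataset(study_inputs, dataset):
    _, _, fabrics, illuminants, receptors = study_inputs
    return build_excitation_dataset(
        fabrics, illuminants, receptors, background=dataset.background_reflectance)


@pytest.fixture(scope="session")
def ensemble_seeds():
    animal_seed, shaded_seed, subset_seed = _derive_seeds(STUDY_SEED + 1, 3)
    return {"animal": animal_seed, "shaded": shaded_seed, "subset": subset_seed}


@pytest.fixture(scope="session")
def animal_ensemble(dataset, ensemble_seeds):
    """Full-protocol animal-vs-leaf ensemble (20 reps × best-of-100)."""
    return run_ensemble(dataset, TaskSpec("animal"),
                        TrainConfig(master_seed=ensemble_seeds["animal"]))


@pytest.fixture(scope="session")
def shaded_ensemble(dataset, ensemble_seeds):
    """Full-protocol shaded-vs-unshaded ensemble (20 reps × best-of-100)."""
    return run_ensemble(dataset, TaskSpec("shaded"),
                        TrainConfig(master_seed=ensemble_seeds["shaded"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """A small generator configuration for cheap structural tests."""
    return GeneratorConfig(n_leaf=12, n_animal=12, seed=5)
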