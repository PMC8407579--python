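import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from taskmap import (
    RDM,
    ActivationMatrix,
    ModelRDMSet,
    PlantedDesign,
    compute_rdm,
    generate_model_rdm_sets,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_rdm(rng, n=6, ids=None):
    """A valid random RDM from random activations."""
    ids = ids or tuple(f"cond_{i:03d}" for i in range(n))
    acts = ActivationMatrix(rng.standard_normal((n, 12)), ids)
    return compute_rdm(acts)


@pytest.fixture
def small_rdm(rng):
    return random_rdm(rng, n=6)


@pytest.fixture
def mixed_design():
    """Three-group design at a small size: 2 models per group + random."""
    return PlantedDesign(
        n_conditions=20,
        group_labels=("2D", "2D", "3D", "3D", "semantic", "semantic", "random"),
        mixture_weights=(1.0, 0, 0, 0, 0, 0, 0),
        n_subjects=6,
        n_voxels=100,
        subject_noise_sd=0.8,
        seed=7,
    )


@pytest.fixture
def mixed_models(mixed_design):
    return generate_model_rdm_sets(mixed_design)
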