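import numpy as np
import pytest

from ihcflow import (
    ClassModelSet,
    GaussianComponent,
    ImageGenConfig,
    MixtureModel,
    generate_ihc_field,
    train_class_models,
)
from ihcflow.synthetic import training_pixels


def make_mixture(rng, n_components=3, scale=255.0, var_range=(20.0, 120.0)):
    """Random valid RGB mixture for property tests."""
    weights = rng.dirichlet(np.ones(n_components))
    comps = []
    for w in weights:
        mean = rng.uniform(0, scale, size=3)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + rng.uniform(*var_range) * np.eye(3)
        comps.append(GaussianComponent(float(w), mean, cov))
    return MixtureModel(comps)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def trained_model_set() -> ClassModelSet:
    """SP/NSP/BG models (5/10/2 components) fit once on synthetic fields."""
    fields = [
        generate_ihc_field(ImageGenConfig(seed=100 + i, fraction_stained=0.4))
        for i in range(3)
    ]
    pixels = {k: v[:2500] for k, v in training_pixels(fields).items()}
    model_set, _ = train_class_models(pixels, seed=7, max_iter=150)
    return model_set
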