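import numpy as np
import pytest

from cephaloseed.landmarks import LandmarkSet
from cephaloseed.registry import LandmarkRegistry
from cephaloseed.synth import ShapeModel, sample_subjects


@pytest.fixture(scope="session")
def registry() -> LandmarkRegistry:
    return LandmarkRegistry.default()


@pytest.fixture(scope="session")
def shape_model(registry) -> ShapeModel:
    return ShapeModel(registry=registry)


@pytest.fixture(scope="session")
def template_set(shape_model) -> LandmarkSet:
    from cephaloseed.synth import template_coords

    return LandmarkSet(template_coords(), frame="canonical",
                       registry=shape_model.registry)


@pytest.fixture(scope="session")
def rasterized_subject(shape_model):
    """One posed, deformed subject with its rasterized volume."""
    return sample_subjects(shape_model, 1, seed=11, with_volumes=True)[0]


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.fixture(scope="session")
def recovery_result():
    """Shared parameter-recovery experiment (VAE latent-dim sweep + Phi).

    Session-scoped: several tests assert different properties of the same
    trained models, so the sweep runs once.
    """
    from cephaloseed.experiments import vae_recovery_experiment

    return vae_recovery_experiment(seed=1)


@pytest.fixture(scope="session")
def pipeline_result():
    """Shared end-to-end coarse-to-fine run on the tiny benchmark."""
    from cephaloseed.experiments import coarse_to_fine_experiment

    return coarse_to_fine_experiment(seed=1)
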