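import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gestaltcohort import Cohort, EmbeddingSet, Gallery, SyntheticConfig, generate_gallery

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_item(image_id, subject_id, vectors, label=None):
    return EmbeddingSet(
        image_id=image_id, subject_id=subject_id, vectors=np.asarray(vectors, float),
        syndrome_label=label,
    )


def random_item(rng, image_id, subject_id="subj", e=3, d=8, label=None):
    return make_item(image_id, subject_id, rng.standard_normal((e, d)), label)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_config():
    """Gallery geometry used throughout: 50 syndromes x 3 subjects x 2 images."""
    return SyntheticConfig(
        n_syndromes=50,
        subjects_per_syndrome=3,
        images_per_subject=2,
        d=64,
        E=3,
        sigma_subject=0.2,
        sigma_image=0.1,
        sigma_ensemble=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_gallery(small_config):
    return generate_gallery(small_config)


@pytest.fixture
def tiny_cohort(rng):
    """Two subjects, three images, E=2, d=4."""
    items = [
        random_item(rng, "a1", "A", e=2, d=4),
        random_item(rng, "a2", "A", e=2, d=4),
        random_item(rng, "b1", "B", e=2, d=4),
    ]
    return Cohort(items)
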