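import numpy as np
import pytest

from histoprog import stain
from histoprog.synthetic_data import (
    CohortSimSpec,
    ImageSimSpec,
    simulate_cohort,
    simulate_he_image,
)


@pytest.fixture(scope="session")
def he_sim():
    """A default synthetic H&E image with its ground-truth stain model."""
    return simulate_he_image(ImageSimSpec(seed=3))


@pytest.fixture(scope="session")
def small_cohort():
    """A cohort with planted class, cluster and survival structure."""
    rng = np.random.default_rng(42)
    beta = np.zeros(30)
    beta[rng.choice(30, 3, replace=False)] = 1.0
    return simulate_cohort(
        CohortSimSpec(
            n_tumor=120,
            n_normal=30,
            n_features=30,
            class_shift=3.0,
            n_clusters=2,
            cluster_shift=3.0,
            survival_beta=beta,
            censor_fraction=0.25,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def reference_model():
    return stain.default_reference()
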