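import numpy as np
import pytest

from cellquant.features import FixtureExtractor
from cellquant.stain import load_reference_stain, od_to_rgb
from cellquant.synth import SynthPatchConfig, generate_patch


@pytest.fixture(scope="session")
def reference_stain():
    return load_reference_stain()


@pytest.fixture(scope="session")
def fixture_extractor():
    return FixtureExtractor(seed=0)


@pytest.fixture(scope="session")
def he_patch():
    """One mid-cellularity synthetic H&E patch."""
    image, achieved = generate_patch(
        SynthPatchConfig(target_cellularity=0.5, seed=11)
    )
    return image


def synth_two_stain_image(reference, rng, n_side=64, near_pure: bool = True):
    """Image mixed from known stain vectors with random concentrations.

    When ``near_pure`` is set, some pixels are almost pure H or pure E so
    the angular-percentile estimator can recover the true vectors.
    """
    n = n_side * n_side
    c = rng.uniform(0.05, 1.2, size=(n, 2))
    if near_pure:
        k = n // 10
        c[:k, 1] = rng.uniform(0, 0.01, size=k)      # nearly pure H
        c[k:2 * k, 0] = rng.uniform(0, 0.01, size=k)  # nearly pure E
    od = c @ reference.stain_matrix
    return od_to_rgb(od.reshape(n_side, n_side, 3)), c


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
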