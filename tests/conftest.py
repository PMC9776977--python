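import numpy as np
import pytest

from adcradiomics.io import ADCImage, ROIMask
from adcradiomics.simulate import CohortSpec, TextureParams


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def flat_image():
    """Constant 20x20 ADC image with a full gland."""
    img = ADCImage(np.full((20, 20), 1000.0), (0.78, 0.78), patient_id="p0")
    gland = ROIMask(np.ones((20, 20), dtype=bool), role="gland")
    return img, gland


@pytest.fixture()
def random_image(rng):
    """Random 20x20 image with an irregular gland mask."""
    pixels = rng.uniform(500.0, 1500.0, size=(20, 20))
    gland = np.zeros((20, 20), dtype=bool)
    rr, cc = np.ogrid[:20, :20]
    gland[((rr - 10) / 9.0) ** 2 + ((cc - 10) / 7.5) ** 2 <= 1] = True
    return ADCImage(pixels, (0.78, 0.78)), ROIMask(gland, role="gland")


@pytest.fixture(scope="session")
def tiny_spec():
    """Scaled-down cohort for fast structural tests (42 lesions / 36 patients).

    Class counts keep >= 5 lesions per class in a 25% test pool so the
    interpolation oversampler remains applicable downstream.
    """
    return CohortSpec(
        n_per_gg={1: 10, 2: 12, 3: 8, 4: 7, 5: 5},
        n_patients=36,
        image_shape=(80, 80),
        gland_radii=(28.0, 24.0),
        area_params={"low": (60.0, 0.5), "high": (80.0, 0.6)},
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    from adcradiomics.simulate import generate_cohort

    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    from adcradiomics.features import build_feature_table

    return build_feature_table(tiny_cohort.slices)
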