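import numpy as np
import pytest

from pneumoseg.imaging import ImageRecord, to_model_input
from pneumoseg.synthetic import PhantomConfig, generate_corpus


@pytest.fixture(scope="session")
def phantom_corpus():
    """Small mixed corpus shared by read-only tests."""
    return generate_corpus(PhantomConfig(image_size=128, n_images=12, positive_fraction=0.5, seed=11))


@pytest.fixture(scope="session")
def training_samples():
    """Eight positive 64px phantoms as ModelInput, for training smoke runs."""
    recs = generate_corpus(
        PhantomConfig(
            image_size=64, n_images=8, positive_fraction=1.0,
            lesion_area_range=(0.02, 0.08), seed=3,
        )
    )
    return [
        to_model_input(ImageRecord(r.image_id, r.image, "png", r.image.shape), r.mask, 64)
        for r in recs
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
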