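import numpy as np
import pytest

from chmmi.detector import DetectorConfig
from chmmi.synthetic import SlideSpec, generate_slide


@pytest.fixture(scope="session")
def small_spec():
    """A small, fast two-class slide spec used across tests."""
    return SlideSpec(
        n_classes=2, image_size=(96, 96), cells_per_image=(1, 3),
        class_weights=(0.6, 0.4), blur_sigma=(0.0, 0.6),
        edge_truncation_prob=0.2, cell_size=(0.2, 0.5), seed=11,
    )


@pytest.fixture(scope="session")
def small_slides(small_spec):
    """Twelve pre-rendered annotated slides."""
    return [generate_slide(small_spec, i) for i in range(12)]


@pytest.fixture(scope="session")
def tiny_config():
    """A 64px three-class detector config with narrow widths."""
    return DetectorConfig(n_classes=3, input_size=(64, 64),
                          widths=(4, 6, 8, 10, 12), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
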