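import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from bbbq.imaging import RasterImage
from bbbq.synthetic import (
    SyntheticImageConfig,
    SyntheticMSIConfig,
    make_brain_image,
    make_msi_dataset,
)


@pytest.fixture(scope="session")
def stained_phantom():
    """Phantom with a strongly stained ipsilateral hemisphere."""
    cfg = SyntheticImageConfig(seed=11, stain_fraction_ipsi=0.8,
                               stain_fraction_contra=0.1)
    return make_brain_image(cfg)


@pytest.fixture(scope="session")
def symmetric_phantom():
    """Unstained phantom: both hemispheres identical by construction."""
    cfg = SyntheticImageConfig(seed=7)
    return make_brain_image(cfg)


@pytest.fixture(scope="session")
def noisy_msi_phantom():
    """MSI phantom with mass error and background, planted ratio 5."""
    cfg = SyntheticMSIConfig(
        seed=13,
        drug_intensity_ipsi=100.0,
        drug_intensity_contra=20.0,
        mass_error_sd_da=0.003,
        n_background_peaks=50,
    )
    return cfg, make_msi_dataset(cfg)


def random_raster(rng, h=16, w=16):
    return RasterImage(rng.integers(0, 256, size=(h, w, 3), dtype=np.uint8))
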