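import numpy as np
import pytest

from gonadquant import PhantomSpec, PipelineConfig, generate_phantom
from gonadquant.synthetic import phantom_reference_and_model


def native_spec(**overrides) -> PhantomSpec:
    """A phantom at the analysis scale (2 um/px, no downsampling)."""
    params = dict(
        height_px=512,
        width_px=512,
        microns_per_pixel=2.0,
        n_tubules=12,
        noise_sd=10.0,
        min_separation_um=16.0,
        seed=7,
    )
    params.update(overrides)
    return PhantomSpec(**params)


@pytest.fixture(scope="session")
def native_config() -> PipelineConfig:
    return PipelineConfig(microns_per_pixel=2.0, downsample_factor=1)


@pytest.fixture(scope="session")
def native_phantom():
    spec = native_spec()
    image, truth = generate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def native_model_ref():
    """Color reference and ST classifier trained on a disjoint phantom."""
    return phantom_reference_and_model(native_spec(seed=555), downsample_factor=1)
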