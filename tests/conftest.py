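import numpy as np
import pytest

from bdaselect import FitnessConfig, SyntheticSpec, generate


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study dataset: 60 x 401, 2 informative bands."""
    return generate(SyntheticSpec())


@pytest.fixture(scope="session")
def noiseless_small():
    """Tiny noiseless 2-component dataset on a 101-channel grid."""
    spec = SyntheticSpec(
        n_samples=24,
        grid=(900.0, 1100.0, 2.0),
        n_components=2,
        band_centers_nm=(950.0, 1050.0),
        band_widths_nm=(20.0, 25.0),
        informative_components=(0, 1),
        coefficients=(1.0, 0.5),
        noise_sd_absorbance=0.0,
        noise_sd_target=0.0,
        seed=42,
    )
    return generate(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def fitness_config_factory():
    def factory(dataset, n_latent=2, k_folds=5, seed=0):
        return FitnessConfig.for_dataset(
            dataset, n_latent=n_latent, k_folds=k_folds, rng=seed
        )

    return factory
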