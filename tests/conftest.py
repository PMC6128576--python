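import dataclasses

import numpy as np
import pytest

from fwhmvasc.phantom import PhantomConfig, default_annotations, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Default acquisition with a fixed seed, shared across tests."""
    cfg = PhantomConfig(seed=42)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Noiseless variant of the default phantom (PSF blur retained)."""
    cfg = PhantomConfig(seed=42, noise_sigma=0.0)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def default_ann(default_phantom):
    cfg, _, _ = default_phantom
    return default_annotations(cfg)


@pytest.fixture()
def small_config():
    """Small, fast config for I/O and CLI tests."""
    return PhantomConfig(
        grid_shape=(40, 40, 40),
        remnant_semiaxes_mm=(3.0, 2.5, 2.0),
        n_phases=6,
        seed=7,
    )


def recovery_configs(n: int = 20):
    """The seeded phantom battery for parameter recovery.

    Remnant largest diameters 6-10 mm, PSF widths 0.4-0.75 mm and noise
    levels giving a peak-enhancement SNR of at least 15.
    """
    rng = np.random.default_rng(123)
    configs = []
    for i in range(n):
        a = rng.uniform(3.0, 5.0)
        configs.append(
            PhantomConfig(
                seed=1000 + i,
                remnant_semiaxes_mm=(a, 0.75 * a, 0.6 * a),
                psf_sigma_mm=rng.uniform(0.4, 0.75),
                noise_sigma=rng.uniform(6.0, 13.0),
            )
        )
    return configs
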