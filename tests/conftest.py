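import numpy as np
import pytest

from nirfusion.synth import (
    default_band_model,
    default_profiles,
    generate_lab_panel,
    generate_spectra,
    inject_missing,
)


@pytest.fixture(scope="session")
def cohort216():
    """Default cohort: 4 cultivars x 54 fruits, 2 replicate spectra each,
    19 fruits with a missing lab value."""
    panel = generate_lab_panel(default_profiles(), 54, seed=1)
    spectra = generate_spectra(panel, seed=2)
    masked = inject_missing(panel, 19, seed=3)
    return masked, spectra


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort with 5x pair band-link contrast: MODE 1 groups are
    spectrally well separated."""
    panel = generate_lab_panel(default_profiles(), 54, seed=11)
    spectra = generate_spectra(
        panel, seed=12, band_model=default_band_model(pair_contrast=5.0)
    )
    masked = inject_missing(panel, 19, seed=13)
    return masked, spectra


@pytest.fixture
def rng():
    return np.random.default_rng(42)
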