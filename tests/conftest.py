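import numpy as np
import pytest

from glycotyper.simulate import (
    CohortSimConfig,
    SpectraSimConfig,
    generate_cohort,
    generate_spectra,
)


@pytest.fixture(scope="session")
def small_spectra_sim():
    """A modest annotated spectra set shared across identification tests."""
    cfg = SpectraSimConfig(n_glyco_spectra=80, n_nonglyco_spectra=80, seed=11)
    return generate_spectra(cfg)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across cohort-level tests."""
    return generate_cohort(CohortSimConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
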