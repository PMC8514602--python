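import numpy as np
import pytest

from swabomics.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small default-structure cohort shared across read-only tests."""
    cfg = CohortConfig(n_subjects=40, visits_per_subject=3, n_features=12, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def three_cst_cohort():
    """Cohort restricted to three sharply distinct community state types."""
    probs = {"I": 0.4, "II": 0.0, "III": 0.35, "IV": 0.25,
             "V": 0.0, "VI": 0.0, "VII": 0.0}
    cfg = CohortConfig(
        n_subjects=60, visits_per_subject=2, cst_initial_probs=probs, seed=5
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_spectra_cohort():
    """Few samples with noiseless synthetic raw spectra for round-trips."""
    cfg = CohortConfig(
        n_subjects=4, visits_per_subject=2, n_features=8,
        feature_mz=np.linspace(100.0, 300.0, 8), seed=1,
        spectrum_mz_range=(90.0, 310.0), spectrum_mz_step=0.005,
        spectrum_n_scans=3,
    )
    return generate_cohort(cfg, with_spectra=True)
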