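import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sleepspectra import association, patterns, synthetic

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic study: 2000 subjects, 88 indicators, seeded."""
    cfg = synthetic.GeneratorConfig(seed=1)
    cohort, spectra, truth = synthetic.generate_cohort(cfg)
    return {"config": cfg, "cohort": cohort, "spectra": spectra, "truth": truth}


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Screens and pattern PCA of the default cohort (shared across tests)."""
    cohort = default_cohort["cohort"]
    spectra = default_cohort["spectra"]
    screen193 = association.screen_psd(cohort, spectra)
    coeffs = patterns.psd_coefficients_48(cohort, spectra)
    pm = {
        state: patterns.pca_of_coefficients(mat, state=state)
        for state, mat in coeffs.items()
    }
    return {
        **default_cohort,
        "screen193": screen193,
        "coeffs": coeffs,
        "patterns": pm,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_raw_generator():
    """A small raw-mode cohort generator for signal-level tests."""
    cfg = synthetic.GeneratorConfig(
        n_subjects=5,
        n_indicators=6,
        seed=11,
        mode="raw",
        raw_minutes=8,
        prevalence_range=(0.2, 0.6),
    )
    return synthetic.CohortGenerator(cfg)
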