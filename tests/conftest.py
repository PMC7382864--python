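import pytest

from birthlink import GeneratorConfig, generate_population


@pytest.fixture(scope="session")
def small_population():
    """Mildly noisy registers: 300-person cohort, 200 births, 60% overlap."""
    cfg = GeneratorConfig(n_cohort=300, n_births=200, seed=42)
    births, cohort, truth = generate_population(cfg)
    return cfg, births, cohort, truth


@pytest.fixture(scope="session")
def clean_population():
    """Zero-noise registers: every overlapping birth copies its mother exactly."""
    cfg = GeneratorConfig(
        n_cohort=250,
        n_births=150,
        typo_rate=0.0,
        missing_mother_dob_rate=0.0,
        municipality_mismatch_rate=0.0,
        covariate_missing_rate=0.0,
        seed=7,
    )
    births, cohort, truth = generate_population(cfg)
    return cfg, births, cohort, truth
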