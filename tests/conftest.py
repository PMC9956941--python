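"""Shared fixtures: small synthetic cohorts generated at test time."""

import warnings

import pytest

from brewlink import (
    PlantedEffect,
    PreprocessConfig,
    SimConfig,
    generate_dataset,
    preprocess_study,
)

# thresholds scaled to the small fixture cohorts
SMALL_PREP = PreprocessConfig(metabolite_min_measurements=10, taxa_min_measurements=3)


@pytest.fixture(scope="session")
def default_cohort():
    """The default study-sized cohort (110 samples) with planted effects."""
    return generate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_prep(default_cohort):
    tables, _ = default_cohort
    return preprocess_study(tables)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """110 samples, two single-driver metabolites with zero noise and no
    censoring: m01 driven by aging year, m02 by the clr abundance of a
    planted species."""
    cfg = SimConfig(
        seed=3,
        noise_sd=0.0,
        censor_quantile=0.0,
        effect_table=[
            PlantedEffect("m01", "aging_year", "linear", +1.0),
            PlantedEffect("m02", "taxon:sp002", "linear", +1.0),
        ],
        n_metabolites=4,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def noiseless_prep(noiseless_cohort):
    tables, _ = noiseless_cohort
    return preprocess_study(tables)


@pytest.fixture(scope="session")
def small_cohort():
    """40 samples, 20 species, 6 pure-noise metabolites: cheap smoke data."""
    cfg = SimConfig(
        n_samples=40,
        n_taxa_species=20,
        n_taxa_genus=8,
        n_metabolites=6,
        effect_table=[],
        seed=5,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_prep(small_cohort):
    tables, _ = small_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return preprocess_study(tables, SMALL_PREP)
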