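"""Shared fixtures: small seeded campaigns generated at test time."""

import pytest

from ciat_triage import GeneratorConfig, curate_campaign, simulate_campaign


@pytest.fixture(scope="session")
def small_config():
    """Two technologies, three artefact-linked assays, fast to simulate."""
    return GeneratorConfig(
        n_compounds=1200,
        technologies=("AlphaScreen", "FRET"),
        n_primary_assays=3,
        n_extra_primary_assays=5,
        target_ciat_prevalence=None,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_campaign(small_config):
    return simulate_campaign(small_config)


@pytest.fixture(scope="session")
def small_datasets(small_campaign):
    return curate_campaign(small_campaign)


@pytest.fixture(scope="session")
def separable_config():
    """Noise-free campaign whose labels equal the motif indicator."""
    return GeneratorConfig(
        n_compounds=1000,
        technologies=("AlphaScreen",),
        n_primary_assays=3,
        n_extra_primary_assays=0,
        p_ciat_given_motif=1.0,
        p_ciat_no_motif=0.0,
        artefact_flip_noise=0.0,
        p_inconclusive=0.0,
        target_ciat_prevalence=None,
        seed=7,
    )


@pytest.fixture(scope="session")
def separable_campaign(separable_config):
    return simulate_campaign(separable_config)


@pytest.fixture(scope="session")
def separable_dataset(separable_campaign):
    return curate_campaign(separable_campaign)["AlphaScreen"]


@pytest.fixture(scope="session")
def pains_catalog():
    from ciat_triage import load_pains_catalog

    return load_pains_catalog()
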