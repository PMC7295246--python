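import pytest

from stagecerna import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A compact dataset with planted structure, shared across tests."""
    config = SimConfig(
        n_lncRNA=30,
        n_miRNA=15,
        n_mRNA=60,
        n_samples_per_stage=25,
        n_planted_triples=8,
        frac_stage_specific=0.5,
        planted_log2fc=2.0,
        planted_correlation=-0.6,
        db_decoy_pairs=40,
        n_terms=10,
        term_size=8,
        n_enriched_terms=2,
        n_prognostic_pan=1,
        n_prognostic_stage=1,
        seed=11,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def null_dataset():
    """No planted effects anywhere: DE, edges and survival are all null."""
    config = SimConfig(
        n_lncRNA=20,
        n_miRNA=10,
        n_mRNA=40,
        n_samples_per_stage=30,
        n_planted_triples=0,
        db_decoy_pairs=60,
        n_prognostic_pan=0,
        n_prognostic_stage=0,
        hazard_coefficient=0.0,
        seed=7,
    )
    return generate_dataset(config)
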