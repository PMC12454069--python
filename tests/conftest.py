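import pytest

from clipsplice.synthetic_data import SimulationConfig, generate_gene_models


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes=8,
        as_events=[
            ("G0001", "alt3p", 0.7, 0.3),
            ("G0004", "es", 0.8, 0.2),
            ("G0005", "ir", 0.2, 0.6),
        ],
        de_genes=[("G0002", 4.0), ("G0003", 0.25)],
        planted_peaks=[
            ("G0006", "3'UTR", 25, "TTA"),
            ("G0007", "intron", 25, "TTA"),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """(fasta, models, gtf, ground truth) for the shared small simulation."""
    return generate_gene_models(small_config)
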