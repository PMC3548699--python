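import pytest
from hypothesis import HealthCheck, settings

from supersage.simulate import (
    SimulationConfig,
    generate_genome,
    generate_transcripts,
    simulate_libraries,
)

settings.register_profile(
    "supersage",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("supersage")


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_chromosomes=4,
        chromosome_length=100_000,
        n_loci=40,
        families={"TPS": 4, "IMP": 3, "P5CS": 2},
        library_depth=100_000,
        # raised structural-class rates so every transcript class is present
        # even in a 40-locus dataset
        frac_no_utr3=0.12,
        frac_cds_only_catg=0.12,
        frac_no_catg=0.08,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Genome, transcripts, four count tables and truth for a small run."""
    genome = generate_genome(small_config)
    transcripts = generate_transcripts(genome, small_config)
    counts, truth = simulate_libraries(transcripts, small_config)
    return genome, transcripts, counts, truth
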