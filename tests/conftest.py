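import pytest

from sixma import synthetic_data as sd


@pytest.fixture(scope="session")
def default_cfg() -> sd.SimConfig:
    return sd.SimConfig(seed=1)


@pytest.fixture(scope="session")
def genome(default_cfg):
    """Annotation + contig lengths for the default config (seed 1)."""
    return sd.simulate_genome(default_cfg)


@pytest.fixture(scope="session")
def tables(default_cfg, genome):
    """(rep1, rep2, sample_compare, truth) for the default config."""
    ann, _ = genome
    return sd.simulate_position_tables(default_cfg, ann)


@pytest.fixture(scope="session")
def small_cfg() -> sd.SimConfig:
    """A quick-to-simulate configuration for tests that re-simulate."""
    return sd.SimConfig(
        seed=3,
        genome=sd.GenomeConfig(contigs=(("c1", 150_000),), genes_per_contig=15),
    )


def noiseless_cfg(seed: int = 11) -> sd.SimConfig:
    """Degenerate config: no replicate noise, constant coverage, no outliers."""
    return sd.SimConfig(
        seed=seed,
        genome=sd.GenomeConfig(contigs=(("c1", 200_000),), genes_per_contig=20),
        methylation=sd.MethylationConfig(replicate_noise_sd=0.0),
        coverage=sd.CoverageConfig(mean=30.0, nb_size=0.0, outlier_fraction=0.0),
    )
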