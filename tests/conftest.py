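import pytest

from serpintools.synthetic_data import generate_genomes, plant_families


@pytest.fixture(scope="session")
def planted_3x5():
    """Three families of five sequences with recorded ground truth."""
    return plant_families(3, 5, seed=101)


@pytest.fixture(scope="session")
def workflow_superfamily():
    """Low-divergence superfamily for alignment-workflow checks: most
    members sit within 2 substitutions of their family consensus."""
    return plant_families(3, 6, within_depth=0.02, indel_rate=0.005, seed=31)


@pytest.fixture(scope="session")
def genome_screen():
    """50 genomes with a planted 20% transfer fraction and a donor-recipient
    GC gap of at least 0.15 (genomes drawn in (0.30, 0.50), donor 0.65)."""
    return generate_genomes(
        n_genomes=50, gc_range=(0.30, 0.50), genes_per_genome=10,
        gene_length=900, hgt_fraction=0.2, donor_gc=0.65, seed=77,
    )
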