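import pytest

from indelmark import (
    SimGenomeConfig,
    SimPopulationConfig,
    implant_indels,
    simulate_population,
    simulate_reference,
)


@pytest.fixture(scope="session")
def toy_genome():
    """Two 120 kb chromosomes with repeats and genes, fixed seed."""
    config = SimGenomeConfig(
        n_chrom=2, chrom_length=120_000, repeat_fraction=0.05,
        gene_fraction=0.3, gc_content=0.36, seed=11,
    )
    return simulate_reference(config)


@pytest.fixture(scope="session")
def implanted(toy_genome):
    """50 InDels on the toy genome with their truth table."""
    reference, repeats, genes = toy_genome
    variants, truth = implant_indels(
        reference, 50, length_range=(1, 15), qual_range=(10.0, 60.0),
        seed=12, repeat_intervals=repeats, gene_intervals=genes,
    )
    return variants, truth


@pytest.fixture(scope="session")
def panel_population():
    """A structured accession panel at the study scale (52 x 63, K=4)."""
    return simulate_population(SimPopulationConfig(seed=33))
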