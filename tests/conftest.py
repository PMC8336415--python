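import numpy as np
import pytest

from clockscape import (GenomeOrder, SimulationConfig, default_pair_table,
                        default_species_table)


@pytest.fixture(scope="session")
def species16():
    return default_species_table()


@pytest.fixture(scope="session")
def pairs120():
    return default_pair_table()


@pytest.fixture
def tiny_order():
    """9 genes on 3 chromosomes."""
    genes = tuple(f"g{i}" for i in range(9))
    return GenomeOrder(genes, {"chr1": (0, 4), "chr2": (4, 7), "chrX": (7, 9)})


@pytest.fixture
def order_500():
    genes = tuple(f"g{i:04d}" for i in range(500))
    return GenomeOrder(genes, {"chr1": (0, 200), "chr2": (200, 350),
                               "chr3": (350, 500)})


@pytest.fixture(scope="session")
def small_sim_config():
    """A scaled-down simulation: same structure, 2,000 genes."""
    return SimulationConfig(
        n_genes=2000,
        chrom_weights_a=tuple([1] * 10),
        chrom_names_a=tuple(f"chr{i}" for i in range(1, 10)) + ("chrX",),
        chrom_weights_b=(3, 2, 2, 1, 1),
        chrom_names_b=("chr1", "chr2", "chr3", "chr4", "chrX"),
        acceleration_blocks=[],
    )
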