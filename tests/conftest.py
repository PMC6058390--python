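import pandas as pd
import pytest

from scglioma import synthetic as syn


@pytest.fixture(scope="session")
def genome():
    return syn.GenomeModel.default()


@pytest.fixture(scope="session")
def tiny_genome():
    """Small genome for fast unit tests: 12 genes per autosome."""
    return syn.GenomeModel.default(
        genes_per_autosome=12, n_mito=4, n_hla=3, n_cell_cycle=4
    )


@pytest.fixture(scope="session")
def branched(genome):
    """A moderate synthetic tumor (branched preset) shared across tests."""
    pops, sets = syn.preset_populations("branched", genome)
    expr, truth = syn.simulate_expression(genome, pops, 600, 2000, seed=11)
    return expr, truth, sets


def make_table(rows):
    """Molecule table from (barcode, umi, gene, reads) tuples."""
    return pd.DataFrame(rows, columns=["barcode", "umi", "gene", "reads"])


@pytest.fixture
def table_factory():
    return make_table
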