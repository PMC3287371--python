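import numpy as np
import pytest

from founderflow import GenotypeTable, HaplotypeSet, SimulationScenario


@pytest.fixture
def two_pop_table() -> GenotypeTable:
    """Two populations, two loci, hand-built genotypes."""
    return GenotypeTable(
        population_ids=["A", "B"],
        locus_ids=["L1", "L2"],
        genotypes={
            "A": [
                [(1, 1), (1, 2)],
                [(1, 2), (2, 2)],
                [(1, 1), (1, 2)],
                [(1, 2), None],
            ],
            "B": [
                [(2, 2), (1, 1)],
                [(2, 3), (1, 2)],
                [(3, 3), (1, 1)],
            ],
        },
    )


@pytest.fixture
def fixed_difference_table() -> GenotypeTable:
    """Each population fixed for a different allele at one locus."""
    return GenotypeTable(
        population_ids=["A", "B"],
        locus_ids=["L1"],
        genotypes={
            "A": [[(1, 1)] for _ in range(10)],
            "B": [[(2, 2)] for _ in range(10)],
        },
    )


@pytest.fixture
def small_hapset() -> HaplotypeSet:
    """Three haplotypes over two populations with known distances."""
    seqs = ["AAAA", "AATA", "CCTA"]
    d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]])
    return HaplotypeSet(
        haplotype_ids=["H1", "H2", "H3"],
        counts={"P1": np.array([12, 3, 0]), "P2": np.array([0, 1, 9])},
        diff_matrix=d,
        sequences=seqs,
        seq_length=4,
    )


@pytest.fixture
def small_scenario() -> SimulationScenario:
    """Reduced-size scenario for fast end-to-end tests."""
    return SimulationScenario(
        n_source_pops=4,
        n_loci=5,
        alleles_per_locus=(4, 10),
        nuclear_sample_sizes=(30, 30, 30, 30, 40),
        mito_sample_sizes=(15, 15, 15, 15, 15),
        true_source="S2",
        true_N0=8,
        K=500,
        seed=11,
    )
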