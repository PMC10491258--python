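import numpy as np
import pandas as pd
import pytest

from ptqtl import syndata
from ptqtl.qtlmap import GenotypeMatrix


@pytest.fixture(scope="session")
def small_config():
    return syndata.SimConfig(
        n_donors=60, n_variants=600, n_edit_sites=60, n_apa_genes=40, seed=7
    )


@pytest.fixture(scope="session")
def small_geno(small_config):
    return syndata.simulate_genotypes(small_config)


@pytest.fixture(scope="session")
def editing_dataset(small_geno, small_config):
    return syndata.simulate_editing_dataset(small_geno, small_config)


@pytest.fixture(scope="session")
def apa_dataset(small_geno, small_config):
    return syndata.simulate_apa_dataset(small_geno, small_config)


@pytest.fixture
def toy_geno():
    """Hand-built 6-donor, 4-variant genotype matrix."""
    donors = [f"d{i}" for i in range(6)]
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3", "v4"],
            "chrom": ["chr1"] * 4,
            "pos": [100, 2_000, 50_000, 120_000],
            "ref": ["A"] * 4,
            "alt": ["G"] * 4,
            "gene_id": ["G1", "G1", "G1", None],
        }
    )
    dosage = np.array(
        [
            [0, 0, 2, 1],
            [0, 1, 1, 0],
            [1, 1, 0, 2],
            [1, 2, 1, 1],
            [2, 0, 0, 0],
            [2, 1, 2, 1],
        ],
        dtype=float,
    )
    return GenotypeMatrix(donors, variants, dosage)
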