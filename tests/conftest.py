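import numpy as np
import pandas as pd
import pytest

from nephromine import synthio
from nephromine.formats import IdentificationTable, ReferenceSet


@pytest.fixture(scope="session")
def small_config():
    return synthio.SimulationConfig(
        seed=1, n_proteins=120, venn_partition=(50, 25, 12, 8),
        n_samples_per_condition=4,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthio.simulate_study(small_config)


@pytest.fixture(scope="session")
def paper_venn_fixture():
    """Reference sets inducing the 613/240/71/57 urine-plasma partition."""
    return synthio.build_paper_venn_fixture((613, 240, 71, 57))


def make_ident_table(sample_id, rows):
    """rows: list of (accession, distinct_peptides, spectral_count)."""
    df = pd.DataFrame(rows, columns=["protein_accession", "distinct_peptides", "spectral_count"])
    df["observed_peptides"] = ""
    return IdentificationTable(sample_id, df)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def refset():
    def make(name, genes):
        return ReferenceSet(name, frozenset(genes))
    return make
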