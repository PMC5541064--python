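import numpy as np
import pytest

from repotrx import ExpressionTable
from repotrx.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_table():
    """3 samples x 4 genes, two drugs."""
    values = np.array(
        [
            [0.5, -1.2, 2.0, 0.1],
            [0.4, -1.0, 1.8, 0.0],
            [-2.0, 0.3, 0.2, 1.5],
        ]
    )
    return ExpressionTable(
        sample_ids=["s1", "s2", "s3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        values=values,
        drug_of_sample={"s1": "dA", "s2": "dA", "s3": "dB"},
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-drug, 120-gene cohort shared by fast downstream tests."""
    spec = SyntheticSpec(
        n_drugs=30, n_genes=120, trials_per_drug=(3, 6), planted_fraction=0.3, seed=7
    )
    table, labels, truth = generate_cohort(spec)
    return spec, table, labels, truth
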