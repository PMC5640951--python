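import numpy as np
import pytest

from pathbench.expression import CONTROL, TREATMENT, ExpressionDataset
from pathbench.genesets import GeneSet, GeneSetCollection
from pathbench.synthetic import default_collection, default_design, generate_dataset


def make_dataset(values, n_treatment, gene_ids=None, sample_ids=None):
    """Build an ExpressionDataset from a genes x samples array; the first
    n_treatment columns are the treatment cohort."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    cohort = tuple(
        TREATMENT if j < n_treatment else CONTROL for j in range(n_samples)
    )
    return ExpressionDataset(
        gene_ids=tuple(gene_ids),
        sample_ids=tuple(sample_ids),
        values=values,
        cohort=cohort,
    )


@pytest.fixture
def tiny_coll():
    """Three small sets over ten genes (g1..g10); g2 is shared."""
    return GeneSetCollection(
        sets=(
            GeneSet("P1", "first", frozenset({"g1", "g2", "g3"})),
            GeneSet("P2", "second", frozenset({"g2", "g4", "g5", "g6"})),
            GeneSet("P3", "third", frozenset({"g7", "g8", "g9", "g10"})),
        )
    )


@pytest.fixture(scope="session")
def fixture_coll():
    """The synthetic fixture collection: 100 disjoint 20-gene sets."""
    return default_collection()


@pytest.fixture(scope="session")
def fixture_dataset(fixture_coll):
    """One realization of the fixture design (2 up-perturbed sets, delta=1)."""
    return generate_dataset(default_design(seed=11), fixture_coll)
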