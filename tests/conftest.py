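import numpy as np
import pandas as pd
import pytest

from tximbalance import synthdata as sd
from tximbalance.foldchange import FoldChangeSet
from tximbalance.ioformats import CountMatrix


@pytest.fixture(scope="session")
def small_spec() -> sd.SyntheticSpec:
    return sd.SyntheticSpec(
        n_genes=800,
        samples_per_group=6,
        depth=2e5,
        seed=11,
        annotations=sd.AnnotationSpec(n_terms=40, term_size_min=8, term_size_max=40),
    )


@pytest.fixture(scope="session")
def small_genes(small_spec):
    return sd.generate_gene_table(small_spec)


@pytest.fixture(scope="session")
def small_counts(small_spec, small_genes):
    counts, effects = sd.generate_counts(small_genes, small_spec)
    return counts, effects


@pytest.fixture()
def toy_counts() -> CountMatrix:
    """3 genes x 4 samples with hand-enterable numbers."""
    counts = pd.DataFrame(
        {
            "young_1": [10, 100, 0],
            "young_2": [12, 90, 2],
            "old_1": [40, 100, 1],
            "old_2": [44, 110, 0],
        },
        index=pd.Index(["gA", "gB", "gC"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "age_group": ["young", "young", "old", "old"],
            "cohort": ["c1", "c2", "c1", "c2"],
            "tissue": ["T1"] * 4,
        },
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountMatrix(counts, samples)


def make_fc(gene_ids, values) -> FoldChangeSet:
    return FoldChangeSet(
        pd.DataFrame({"log2fc": np.asarray(values, dtype=float)}, index=pd.Index(gene_ids))
    )
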