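import numpy as np
import pandas as pd
import pytest

from mycnsig import synthetic
from mycnsig.io import ExpressionMatrix, PathwayDB, SampleTable


@pytest.fixture
def small_spec():
    """A 60-sample, 40-gene cohort with 8 planted markers."""
    genes = tuple(f"G{i:03d}" for i in range(40))
    return synthetic.CohortSpec(
        n_samples=60,
        frac_amplified=0.25,
        n_genes=40,
        gene_ids=genes,
        marker_genes=genes[:8],
        effect_log2=2.0,
        noise_sd_log2=0.5,
        n_controls=6,
        seed=7,
        cohort="toy",
    )


@pytest.fixture
def small_cohort(small_spec):
    return synthetic.generate_cohort(small_spec)


@pytest.fixture
def toy_expression():
    """3 genes x 4 samples with hand-checkable values."""
    data = pd.DataFrame(
        [[8.0, 2.0, 6.0, 4.0], [1.0, 1.0, 1.0, 1.0], [10.0, 20.0, 5.0, 40.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "c1", "c2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def toy_samples():
    return SampleTable(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "c1", "c2"],
                "mycn_status": ["amplified", "wild_type", "unknown", "unknown"],
                "group": ["tumor", "tumor", "control", "control"],
                "cohort": ["toy", "toy", "ctrl", "ctrl"],
            }
        )
    )


@pytest.fixture
def toy_db():
    return PathwayDB(
        pd.DataFrame(
            {
                "pathway": ["P1", "P2", "P2"],
                "gene": ["gA", "gA", "gC"],
                "arr": [1.0, 1.0, -1.0],
            }
        )
    )
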