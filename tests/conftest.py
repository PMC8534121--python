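import numpy as np
import pandas as pd
import pytest

from metintegrate import synthdata
from metintegrate.containers import ExpressionMatrix


@pytest.fixture
def small_tissue():
    """1000-gene cohort with 50 genes planted upregulated in metastasis."""
    em, truth = synthdata.generate_tissue_expression(
        n_genes=1000, n_per_class=(10, 20, 10), n_de=50,
        effect_size=2.0, noise_sd=0.5, seed=7)
    return em, truth


@pytest.fixture
def tiny_matrix():
    """Hand-built 3-gene, 6-sample matrix with two classes."""
    values = pd.DataFrame(
        np.arange(18, dtype=float).reshape(3, 6),
        index=["GA", "GB", "GC"],
        columns=[f"S{i}" for i in range(6)],
    )
    classes = pd.Series(["primary"] * 3 + ["metastasis"] * 3, index=values.columns)
    return ExpressionMatrix(values=values, sample_class=classes)
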