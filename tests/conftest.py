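import numpy as np
import pandas as pd
import pytest

from actsig.datamodel import (
    ClinicalTable,
    CohortBundle,
    CopyNumberMatrix,
    GeneExpressionMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_expression(rng):
    """50 genes x 20 samples of log2-scale noise."""
    genes = [f"G{i:03d}" for i in range(50)]
    samples = [f"S{i:02d}" for i in range(20)]
    vals = pd.DataFrame(rng.normal(8, 1, (50, 20)), index=genes, columns=samples)
    return GeneExpressionMatrix(vals)


def make_cohort(rng, n=40, n_genes=30, driver="YAP1"):
    """Tiny cohort with a dosage-coupled driver for screen tests."""
    genes = [driver] + [f"G{i:03d}" for i in range(n_genes - 1)]
    samples = [f"S{i:03d}" for i in range(n)]
    gistic = rng.choice([-1, 0, 1, 2], size=n, p=[0.1, 0.5, 0.2, 0.2])
    x = rng.normal(0, 1, (n_genes, n))
    x[0] = gistic + rng.normal(0, 0.3, n)
    expr = GeneExpressionMatrix(pd.DataFrame(x, index=genes, columns=samples))
    cn = CopyNumberMatrix(pd.DataFrame(
        np.vstack([gistic, rng.choice([-1, 0, 1], size=(n_genes - 1, n))]),
        index=genes, columns=samples))
    clin = ClinicalTable(pd.DataFrame({
        "os_time": rng.exponential(40, n),
        "os_event": rng.integers(0, 2, n),
        "sex": rng.choice(["male", "female"], n),
    }, index=samples))
    return CohortBundle(name="tiny", expression=expr, clinical=clin, cn=cn)


@pytest.fixture
def tiny_cohort(rng):
    return make_cohort(rng)
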