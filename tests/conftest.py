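import numpy as np
import pandas as pd
import pytest

from itscore import (
    ClinicalTable,
    CohortConfig,
    ExpressionMatrix,
    GeneSet,
    generate_cohort,
)

# compact generator settings shared by tests that only need a cohort with
# planted structure, not the full-size study conditions
SMALL_COHORT = dict(
    n_samples=120,
    n_genes=400,
    n_ctl_only=25,
    n_overlap=25,
    n_tmb_only=25,
    n_tgfb=15,
)


@pytest.fixture(scope="session")
def planted_cohort():
    """Default-condition cohort (300 x 2000, effect_r 0.5) built once."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(CohortConfig(seed=7, **SMALL_COHORT))


@pytest.fixture
def tiny_expr():
    """5 genes x 4 samples, log scale, hand-enterable values."""
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.uniform(0, 8, size=(5, 4)),
        index=[f"g{i}" for i in range(5)],
        columns=[f"s{j}" for j in range(4)],
    )
    return ExpressionMatrix(df, log_transformed=True)


def random_small_instance(rng):
    """A <=10-gene x <=5-sample matrix and a proper gene subset."""
    g = rng.integers(3, 11)
    n = rng.integers(1, 6)
    vals = rng.uniform(0, 10, size=(g, n))
    if rng.random() < 0.3:  # force expression ties sometimes
        vals = np.round(vals, 0)
    genes = [f"g{i:02d}" for i in range(g)]
    m = rng.integers(1, g)
    set_genes = list(rng.choice(genes, size=m, replace=False))
    df = pd.DataFrame(vals, index=genes, columns=[f"s{j}" for j in range(n)])
    return ExpressionMatrix(df, log_transformed=True), set_genes
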