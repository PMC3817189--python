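import numpy as np
import pytest

import cgsa
from cgsa.exprio import ExpressionMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230929)


@pytest.fixture(scope="session")
def small_matrix():
    """Random 5-gene, 8-sample matrix for formula oracles."""
    r = np.random.default_rng(42)
    return ExpressionMatrix(
        [f"G{i}" for i in range(1, 6)],
        [f"S{j}" for j in range(1, 9)],
        r.normal(8, 1, (5, 8)),
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort from the acceptance-scale default design."""
    design = cgsa.default_design()
    return cgsa.simulate_cohort(design, seed=7)


@pytest.fixture(scope="session")
def fitted_cohort(default_cohort):
    """Cohort plus its extracted collection and summary matrix."""
    X, pheno, truth = default_cohort
    coll = cgsa.extract_cgs_collection(X, n_sets=10, r_min=0.6)
    S = cgsa.summarize_cgs(X, coll)
    return X, pheno, truth, coll, S
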