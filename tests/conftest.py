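import numpy as np
import pytest

from traumacpm import pipeline, simulate


@pytest.fixture(scope="session")
def default_cohort():
    """The default planted-effect cohort (n=160, 60 nodes, seed 7)."""
    return simulate.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def default_cohort_xy(default_cohort):
    """Modeled arrays for the 1-month target of the default cohort."""
    kept, e, y, X = pipeline.assemble(default_cohort.edges,
                                      default_cohort.phenotype, "1m")
    return e, y, X


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
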