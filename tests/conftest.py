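import numpy as np
import pytest

from ovca.io_formats import ExpressionMatrix
from ovca.simulate import CohortSimConfig, simulate_cohort


@pytest.fixture
def tiny_expr():
    return ExpressionMatrix(
        ["TP53", "BRCA1"],
        ["s1", "s2"],
        np.array([[1.5, -0.25], [2.0, 3.0]]),
    )


@pytest.fixture(scope="session")
def planted_cohort():
    """Three clear subtypes, moderate size; shared across read-only tests."""
    cfg = CohortSimConfig(
        n_genes=200,
        n_samples=90,
        k_subtypes=3,
        genes_per_signature=25,
        signature_effect=2.0,
        noise_sd=0.5,
        rng_seed=11,
    )
    return simulate_cohort(cfg)
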