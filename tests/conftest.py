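import numpy as np
import pytest

import fedcog as fc


@pytest.fixture(scope="session")
def cohort_2239() -> fc.FeatureTable:
    """The canonical cohort size: 2,239 participants at 9.9% CU prevalence."""
    return fc.generate_cohort(fc.GeneratorConfig(n_samples=2239, seed=11))


@pytest.fixture()
def small_table() -> fc.FeatureTable:
    """A tiny mixed-class table for fast unit tests."""
    rng = np.random.default_rng(5)
    n = 40
    labels = np.array([0] * 8 + [1] * 32)
    return fc.FeatureTable(
        features=rng.standard_normal((n, 6)),
        labels=labels,
        sample_ids=np.array([f"id{i}" for i in range(n)], dtype=object),
    )


@pytest.fixture()
def toy_params() -> fc.ModelParams:
    return fc.init_params((6, 4, 1), seed=3)
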