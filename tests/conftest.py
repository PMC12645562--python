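import numpy as np
import pytest

from lactrace.simulate import FluxConfig, default_group_configs, emit_cohort, ground_truth_mids


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def default_truth():
    """Ground-truth MIDs for the default cohort design (solved once per session)."""
    return ground_truth_mids(default_group_configs())


@pytest.fixture(scope="session")
def clean_cohort(default_truth):
    """A noise-free, natural-abundance-free cohort: emitted fractions are the truth."""
    mids, truth = emit_cohort(
        n_animals=2, noise_cv=0.0, seed=11, p13=0.0, tracer_purity=1.0,
        ground_truth=default_truth,
    )
    return mids, truth


@pytest.fixture(scope="session")
def realistic_cohort(default_truth):
    """A small cohort with natural abundance and 5% multiplicative noise."""
    mids, truth = emit_cohort(
        n_animals=5, noise_cv=0.05, seed=7, ground_truth=default_truth,
    )
    return mids, truth
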