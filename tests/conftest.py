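import numpy as np
import pytest

from temponet import BVARParams, CohortSpec, simulate_cohort_panel
from temponet.preprocess import reference_to_baseline


@pytest.fixture
def default_params():
    return BVARParams()


@pytest.fixture
def null_params():
    """Independent AR(1) pair: no causal coefficient."""
    return BVARParams(c_mean=0.0, c_sd=0.0)


@pytest.fixture
def chain_truth():
    """5-gene cohort with one strong inter-slice edge g0 -> g1."""
    genes = [f"g{i}" for i in range(5)]
    spec = CohortSpec(
        genes=genes,
        inter_edges={("g0", "g1"): 1.0},
        noise_sd=0.05,
        baseline_sd=1.0,
    )
    return simulate_cohort_panel(spec, 40, 7, seed=123)


@pytest.fixture
def chain_panel(chain_truth):
    return reference_to_baseline(chain_truth.panel)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
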