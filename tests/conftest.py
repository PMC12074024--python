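import numpy as np
import pytest

from moeclock import CohortSpec, MoEConfig, generate_cohort, init_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_model():
    """Small MoE with dropout off: deterministic in train mode too."""
    config = MoEConfig(input_dim=8, n_experts=2, hidden_widths=(6, 4),
                       dropout_rate=0.0, seed=7)
    return init_model(config)


@pytest.fixture
def small_cohort():
    """A quick synthetic cohort with one accelerated-aging disease group."""
    spec = CohortSpec(n_healthy=120, disease_groups=[("dz", 60, 10.0)], d_genes=200,
                      n_causal=30, pool_size=40, noise_sd=1.0, seed=1)
    return generate_cohort(spec)
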