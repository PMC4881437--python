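import numpy as np
import pytest

from crcmet.pipeline import PipelineConfig, run_pipeline
from crcmet.simulate import SimConfig, simulate_cohort, simulate_expression


@pytest.fixture(scope="session")
def default_cohort():
    """Default 96-sample synthetic cohort, fixed seed."""
    cfg = SimConfig(seed=11)
    profiles, clinical, truth = simulate_cohort(cfg)
    return cfg, profiles, clinical, truth


@pytest.fixture(scope="session")
def default_expression(default_cohort):
    cfg, _, _, truth = default_cohort
    expr, meta = simulate_expression(cfg, truth)
    return expr, meta, truth


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default synthetic cohort."""
    cfg = PipelineConfig(n_perm=499, emt_n_perm=500, seed=0)
    return cfg, run_pipeline(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
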