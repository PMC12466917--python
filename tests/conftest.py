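import numpy as np
import pytest

from phagescreen.pipeline import PipelineConfig, run_pipeline
from phagescreen.synth import CohortConfig, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """20-phage cohort with half the phages carrying a planted ARG."""
    return generate_cohort(CohortConfig(n_phages=20, seed=7, planted_arg_rate=0.5))


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    """Full pipeline result on the 20-phage cohort (no files written)."""
    cfg = PipelineConfig(seed=7, cohort={"n_phages": 20, "seed": 7, "planted_arg_rate": 0.5})
    return run_pipeline(cfg, cohort=small_cohort, write=False)


@pytest.fixture(scope="session")
def parab_cohort():
    """Temperate-rich cohort with parA/parB carriers and integrations."""
    return generate_cohort(
        CohortConfig(
            n_phages=30,
            seed=11,
            lytic_fraction=0.4,
            parab_rate=0.5,
            planted_arg_rate=0.3,
        )
    )
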