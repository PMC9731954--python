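import numpy as np
import pytest

from ncptkit.simulate import CohortConfig, simulate_cohort, simulate_scores_fast


@pytest.fixture(scope="session")
def contaminated_cohort():
    """Trial-level battery-39 cohort with every contamination type injected."""
    cfg = CohortConfig(n=400, battery_id=39, pause_rate=0.05,
                       interleave_rate=0.03, slow_trails_rate=0.02,
                       dropout_rate=0.05)
    return simulate_cohort(cfg, 20_240)


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean trial-level cohort on battery 17 (no trails, no defects)."""
    return simulate_cohort(CohortConfig(n=250, battery_id=17), 7)


@pytest.fixture(scope="session")
def fast_cohort():
    """Large clean score-level cohort on battery 39 for distributional checks."""
    scores, truth = simulate_scores_fast(CohortConfig(n=20_000, battery_id=39), 99)
    return scores, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
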