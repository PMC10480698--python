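import warnings

import numpy as np
import pytest

from metacog import cohort, sdt_core, survey_io

warnings.filterwarnings("ignore", message=".*ArviZ.*")


def type1_estimates(counts):
    """Fast padded type-1 estimates for every (respondent, domain)."""
    return {k: sdt_core.estimate_type1(cc.counts) for k, cc in counts.items()}


@pytest.fixture(scope="session")
def small_cohort():
    """One small synthetic study shared by read-only tests."""
    cfg = cohort.CohortConfig(n_subjects=60, items_per_domain=14, seed=12345)
    return cohort.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_counts(small_cohort):
    responses, _, _ = small_cohort
    return survey_io.tabulate_counts(responses)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
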