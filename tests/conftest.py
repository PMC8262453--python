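import numpy as np
import pytest

from tempoclust.datatypes import PipelineConfig
from tempoclust.pipeline import join_accepted_trials
from tempoclust.preprocess import clean_cohort
from tempoclust.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210531)


@pytest.fixture(scope="session")
def small_cohort():
    """400-participant clean cohort with modest contamination, seed-fixed."""
    cfg = SimConfig(
        n_participants=400,
        seed=11,
        repeat_rate=0.03,
        fast_rate=0.01,
        age_outlier_rate=0.01,
        invalid_rate=0.005,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def cleaned_points(small_cohort):
    """(mean ITI, CV) feature matrix of the cleaned small cohort."""
    ds, _ = small_cohort
    cfg = PipelineConfig(seed=11)
    kept, audit = clean_cohort(join_accepted_trials(ds, cfg), cfg)
    pts = np.column_stack(
        [[r.summary.mean_iti for r in kept], [r.summary.cv for r in kept]]
    )
    return kept, pts, audit
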