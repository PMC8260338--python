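import numpy as np
import pytest
from hypothesis import settings

from plgfbind import BiomarkerSample, SimConfig, simulate_cohort

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

#: Group sizes matching the study cohort with 42 usable antepartum samples.
STUDY_GROUP_SIZES = {"no_pe": 11, "pe": 13, "hellp": 12, "aflp": 6}


@pytest.fixture
def rng():
    return np.random.default_rng(20210628)


@pytest.fixture
def noise_free_cohort():
    """42 mechanistic samples at K_D = 50 pmol/L with no measurement noise."""
    cfg = SimConfig(seed=7, mode="mechanistic_from_free", kd=50.0, noise_cv=0.0)
    return simulate_cohort(STUDY_GROUP_SIZES, cfg)


@pytest.fixture
def aflp_median_sample():
    """A sample carrying the AFLP group medians (sFlt-1 77762, free PlGF 208 pg/mL)."""
    return BiomarkerSample(sample_id="aflp-median", group="aflp", sflt1=77_762.0, free_plgf=208.0)
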