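import numpy as np
import pytest

from ipgbp import synthetic as syn
from ipgbp.pipeline import RunConfig, subject_feature_set, run_subject_end_to_end


@pytest.fixture(scope="session")
def default_profile():
    return syn.generate_subject(0)


@pytest.fixture(scope="session")
def quiet_profile():
    """Noise-free, jitter-relevant profile for oracle tests."""
    return syn.SubjectProfile(
        subject_id="quiet", baseline_SBP=120.0, baseline_DBP=70.0,
        trial_sd=0.0, heart_rate=1.2, noise_snr=np.inf, cuff_noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def default_feature_set():
    """Images + references of the default synthetic subject (seed 0)."""
    return subject_feature_set(0, RunConfig())


@pytest.fixture(scope="session")
def end_to_end_run(default_feature_set):
    """Full default-subject pipeline run: train, predict, evaluate (seed 0)."""
    return run_subject_end_to_end(0, RunConfig(), feature_set=default_feature_set)
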