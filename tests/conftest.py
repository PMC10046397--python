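import numpy as np
import pytest

from ppgbp.features import build_feature_matrix
from ppgbp.synth import SubjectProfile, synth_recording


@pytest.fixture
def profile():
    """A normotensive resting subject."""
    return SubjectProfile("subj", sbp_true=120.0, dbp_true=80.0, heart_rate=65.0)


@pytest.fixture
def clean_recording(profile):
    """30 s of noiseless PPG with the generator's beat-onset log attached."""
    return synth_recording(profile, 30.0, "noiseless", rng_seed=11)


@pytest.fixture(scope="session")
def small_cohort_features():
    """Features + ground truth from a handful of excellent-quality subjects."""
    rng = np.random.default_rng(99)
    recs = []
    for i in range(8):
        p = SubjectProfile(
            f"c{i}",
            sbp_true=float(rng.uniform(100, 135)),
            dbp_true=float(rng.uniform(60, 85)),
            heart_rate=float(rng.uniform(55, 75)),
        )
        recs.append(synth_recording(p, 31.0, "excellent", rng_seed=int(rng.integers(2**31))))
    return build_feature_matrix(recs)
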