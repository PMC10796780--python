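import numpy as np
import pandas as pd
import pytest

from hrfprobe.hrf import GroupHRFOffsets
from hrfprobe.simulate import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small noiseless-jitter cohort shared by read-only tests."""
    cfg = CohortConfig(n_per_group=4, noise_sd=0.5,
                       amplitude_jitter_frac=0.0, latency_jitter_s=0.0)
    return simulate_cohort(cfg, rng_seed=7)


@pytest.fixture()
def balanced_metadata():
    """20 subjects, 10 per group, with exact cross-group age/gender twins."""
    rows = []
    for i in range(10):
        age = 45.0 + i
        gender = "F" if i % 2 else "M"
        rows.append((f"sub-{i:03d}", "control", age, gender))
        rows.append((f"sub-{i + 10:03d}", "patient", age, gender))
    return pd.DataFrame(rows, columns=["subject_id", "group", "age",
                                       "gender"])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
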