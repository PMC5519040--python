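import numpy as np
import pandas as pd
import pytest

from crgmet import generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """Full-size synthetic cohort with the study-like planted structure."""
    data, truth = generate_dataset(seed=0)
    return data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def volume_table():
    """Dual-observer baseline volumes for four patients, one discordant."""
    rows = []
    crg = {"A": (1.10, 1.10), "B": (1.30, 1.00), "C": (0.90, 0.95), "D": (1.00, None)}
    for pid, (c1, c2) in crg.items():
        rows.append(("P" + pid, "obs1", "baseline", 150.0 * c1, 150.0, 40.0))
        if c2 is not None:
            rows.append(("P" + pid, "obs2", "baseline", 150.0 * c2, 150.0, 40.0))
    return pd.DataFrame(rows, columns=["patient_id", "observer_id", "timepoint", "vc_cc", "vi_cc", "vtumor_cc"])
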